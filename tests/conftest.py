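import numpy as np
import pytest

from chronoswitch.io_formats import TimeCourseMatrix, TranscriptModel, DomainLibrary


@pytest.fixture
def quant_file(tmp_path):
    """A hand-written Salmon-dialect quantification table."""
    path = tmp_path / "quant.sf"
    path.write_text(
        "Name\tLength\tEffectiveLength\tTPM\tNumReads\n"
        "TX1\t1000\t900.0\t10.0\t90.0\n"
        "TX2\t500\t400.0\t0.0\t0.0\n"
    )
    return path


@pytest.fixture
def small_matrix():
    """Two genes: one antiphase switching pair, one proportional pair."""
    times = np.arange(0.0, 31.0, 3.0)
    s = np.sin(2 * np.pi * times / 24.0 + np.pi / 3)
    values = np.vstack([
        10 + 5 * s,          # GA.T1
        10 - 5 * s,          # GA.T2
        8 + 2 * s,           # GB.T1
        0.5 * (8 + 2 * s),   # GB.T2 proportional, never crosses T1
    ])
    return TimeCourseMatrix(
        transcript_ids=["GA.T1", "GA.T2", "GB.T1", "GB.T2"],
        times=times,
        values=values,
        tx2gene={"GA.T1": "GA", "GA.T2": "GA", "GB.T1": "GB", "GB.T2": "GB"},
    )


def make_model(transcript_id="TX", gene_id="G", strand="+", exons=((0, 100),),
               sequence=None, **kw):
    return TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, strand=strand,
        exons=tuple(exons), sequence=sequence, **kw,
    )


@pytest.fixture
def domain_lib():
    return DomainLibrary(entries=[("MK-motif", "MK"), ("KA-motif", "KA")])
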