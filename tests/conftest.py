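import numpy as np
import pytest

from tilechip.genome import Feature, GenomeAnnotation
from tilechip.tiling import SmoothedTrack


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Hand-built two-chromosome annotation for coordinate-level tests."""
    features = [
        Feature("YA1", "chrI", 1000, 3000, "+", "ORF", expression_level=2000.0, gc_fraction=0.42),
        Feature("YA2", "chrI", 4000, 5000, "-", "ORF", expression_level=800.0, gc_fraction=0.38),
        Feature("YA3", "chrI", 6000, 8000, "+", "ORF", expression_level=500.0, gc_fraction=0.35),
        Feature("YB1", "chrII", 500, 2500, "-", "ORF", expression_level=5000.0, gc_fraction=0.45),
        Feature("CEN1", "chrI", 5200, 5320, ".", "centromere"),
        Feature("TEL01", "chrI", 0, 300, ".", "telomere"),
        Feature("ARS_001", "chrI", 3400, 3600, ".", "ARS"),
        Feature("intron_001", "chrI", 1400, 1500, "+", "intron"),
        Feature("tR1", "chrII", 3000, 3100, "+", "RNAPIII"),
    ]
    return GenomeAnnotation({"chrI": 10_000, "chrII": 6_000}, features)


def make_smoothed(positions, signal, p_value, chrom="chrI", bandwidth=150):
    return SmoothedTrack(
        chrom,
        np.asarray(positions, dtype=np.int64),
        np.asarray(signal, dtype=float),
        np.asarray(p_value, dtype=float),
        bandwidth,
    )
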