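import numpy as np
import pytest

from genesat.synthetic_data import make_ld


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def ar1_10():
    """AR(1) LD matrix, r = 0.5, m = 10."""
    return make_ld("ar1", 10, r=0.5).r


def write_sumstats(path, rows, header=("SNP", "CHR", "BP", "A1", "A2", "OR", "SE", "INFO")):
    """Write a small summary-statistics fixture file."""
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


COLUMN_MAP = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "odds_ratio": "OR",
    "se": "SE",
    "info": "INFO",
}
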