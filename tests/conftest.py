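import numpy as np
import pandas as pd
import pytest

from lampyrid import simulate


@pytest.fixture(scope="session")
def coverage_sim():
    """Small coverage dataset: 1 X + 7 autosomes, 60 windows each."""
    contigs = [simulate.ContigSpec("ctgX", 600_000, "X")] + [
        simulate.ContigSpec(f"ctg{i}", 600_000, "A") for i in range(1, 8)
    ]
    cfg = simulate.CoverageSimConfig(contigs=contigs, depth=80.0, seed=11)
    cov, truth = simulate.simulate_coverage(cfg)
    return cov, truth


@pytest.fixture(scope="session")
def counts_sim():
    """Counts with planted bias, full X compensation, 5 replicates/sex."""
    cfg = simulate.ExpressionSimConfig(
        n_genes=1500,
        replicates=5,
        effect_size_range=(3.0, 6.0),
        seed=7,
    )
    return simulate.simulate_counts(cfg)


@pytest.fixture()
def toy_coverage():
    """Hand-built coverage table: 11 contigs, 1 sample/sex, constant depth.

    ctg1..ctg10 are diploid everywhere; ctgX has male counts at half the
    female level. All contigs are 100 kb with 10 windows. Values are
    tie-free by construction: autosomal male/female windows interleave
    (no separation), X male windows sit fully below the female range.
    """
    rows = []
    for contig, male_level in [(f"ctg{i}", 100) for i in range(1, 11)] + [
        ("ctgX", 50)
    ]:
        for w in range(10):
            start, end = w * 10_000, (w + 1) * 10_000
            count_f = 100 + 2 * w
            count_m = 101 + 2 * w if male_level == 100 else 50 + w
            rows.append((contig, start, end, "f1", "female", count_f))
            rows.append((contig, start, end, "m1", "male", count_m))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "sample", "sex", "count"]
    )
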