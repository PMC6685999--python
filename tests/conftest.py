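import pytest

from noarewire import synthetic
from noarewire.iotypes import GenomeModel
from noarewire.preprocess import correct_covariates, filter_genes, normalize
from noarewire.iotypes import ExpressionMatrix
from noarewire.stress import StressGrouping, StressThresholds


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeModel(("chr1", "chr2"), (1_000_000, 1_000_000))


@pytest.fixture(scope="session")
def planted_bundle():
    """Standard planted fixture: 500 genes, 60+60 samples, 3 modules
    (r_low 0.7 / r_high 0.0), 2 hubs with 5 neighbours at log2FC 1."""
    return synthetic.simulate_fixture(n_genes=500, n_low=60, n_high=60, seed=11)


@pytest.fixture(scope="session")
def planted_expression(planted_bundle):
    """Filtered, normalized, covariate-corrected expression plus grouping."""
    expr = planted_bundle["expression"]
    meta = planted_bundle["meta"]
    grouping = StressGrouping(
        labels=meta.table["stress_label"],
        thresholds=StressThresholds(0.070, 0.192),
        min_group=0,
    )
    report = filter_genes(expr)
    norm = normalize(ExpressionMatrix(values=expr.values.loc[report.kept], value_kind="raw"))
    resid = correct_covariates(norm, meta, ["age", "sex"])
    return resid, grouping
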