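import numpy as np
import pytest

from oxiscore import PipelineConfig, build_reference_fixture, run_pipeline
from oxiscore.core_model import GenotypePanel, Variant


def make_panel(rows, chrom="1", start=1_000_000, spacing=10_000):
    """Panel from raw genotype rows (lists of 0/1/2/-1), one per variant."""
    rows = np.asarray(rows, dtype=np.int8)
    variants = [
        Variant(chrom=chrom, pos=start + i * spacing, allele_a="A", allele_b="G",
                rsid=f"rs{i + 1}")
        for i in range(rows.shape[0])
    ]
    samples = [f"S{j + 1}" for j in range(rows.shape[1])]
    return GenotypePanel(samples=samples, variants=variants, genotypes=rows)


def grid_oracle(counts, res=4001):
    """Profile-likelihood grid search over the one free haplotype frequency.

    Independent check for the EM: allele frequencies are fixed at their
    observed values (stationary under the EM update); the cis-haplotype
    frequency is scanned over its feasible range and the multinomial
    log-likelihood of the 3x3 genotype table maximised directly.
    Returns (best cis frequency, best log-likelihood).
    """
    n = np.asarray(counts, dtype=float)
    two_n = 2 * n.sum()
    pa = (2 * n[2, :].sum() + n[1, :].sum()) / two_n
    pb = (2 * n[:, 2].sum() + n[:, 1].sum()) / two_n
    lo, hi = max(0.0, pa + pb - 1), min(pa, pb)
    p11 = np.linspace(lo, hi, res)
    p10 = pa - p11
    p01 = pb - p11
    p00 = 1 - pa - pb + p11
    eps = 1e-300
    cells = [
        (p11**2, (2, 2)), (2 * p11 * p10, (2, 1)), (p10**2, (2, 0)),
        (2 * p11 * p01, (1, 2)), (2 * (p11 * p00 + p10 * p01), (1, 1)),
        (2 * p10 * p00, (1, 0)), (p01**2, (0, 2)), (2 * p01 * p00, (0, 1)),
        (p00**2, (0, 0)),
    ]
    ll = sum(n[idx] * np.log(np.maximum(arr, eps)) for arr, idx in cells)
    i = int(np.argmax(ll))
    return float(p11[i]), float(ll[i])


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """The curated demonstration bundle, run through the full pipeline once."""
    d = tmp_path_factory.mktemp("fixture")
    paths, truth = build_reference_fixture(d, seed=0)
    cfg = PipelineConfig(
        gwas=paths["gwas"], qtls=paths["qtls"], consequences=paths["consequences"],
        panel=paths["panel"], pathways=paths["pathways"], drugs=paths["drugs"],
        adme=paths["adme"], out_dir=str(d / "out"),
    )
    report = run_pipeline(cfg)
    return paths, truth, report
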