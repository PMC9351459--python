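import numpy as np
import pandas as pd
import pytest

from steeproot.mutations import GeneModel

# toy gene: two exons on +, CDS = ATG GCT TAA split across the intron
# genome:            1234567890123456789012
#                    ATGGC-------TTAA
TOY_GENOME = {"chrT": "ATGGCGTAAGTTTTTTTTCAGTTAACCGGTT"}
# exon1 1-5 (ATGGC), intron 6-21, exon2 22-25 (TTAA); CDS = ATGGC + TTAA? (9 nt)
TOY_GENE = GeneModel(
    gene_id="toy",
    chrom="chrT",
    strand="+",
    exons=((1, 5), (22, 25)),
    cds=((1, 5), (22, 25)),
)


@pytest.fixture
def toy_gene():
    return TOY_GENE


@pytest.fixture
def toy_genome():
    return TOY_GENOME


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_filter_panel(rng, n_variants=50, n_samples=8):
    """Random variant x sample depth table for exercising the panel filter."""
    samples = [f"s{i}" for i in range(n_samples)]
    rows = []
    for i in range(n_variants):
        per = {}
        for s in samples:
            dp = int(rng.integers(0, 30))
            per[s] = (dp, int(rng.integers(0, dp + 1)) if dp else 0)
        rows.append(("chr1", 10 + i, "G", "A", float(rng.uniform(20, 80)), per))
    return panel_frame(rows, samples), samples


def brute_force_filter(panel, samples, focal, cfg):
    """Plain re-evaluation of the retention predicate, row by row."""
    keep = []
    for _, row in panel.iterrows():
        ok = row["qual"] > cfg.min_qual
        for s in samples:
            dp, dv = row[f"DP_{s}"], row[f"DV_{s}"]
            if dp < cfg.min_dp:
                ok = False
                break
            ratio = dv / dp
            if s in focal and ratio < cfg.min_focal_ratio:
                ok = False
                break
            if s not in focal and ratio > cfg.max_other_ratio:
                ok = False
                break
        keep.append(ok)
    return panel.loc[keep, "pos"].tolist()


def panel_frame(rows, samples):
    """Build a variant-panel DataFrame from (chrom,pos,ref,alt,qual,{s:(dp,dv)}) rows."""
    out = []
    for chrom, pos, ref, alt, qual, persample in rows:
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "qual": qual}
        for s in samples:
            dp, dv = persample[s]
            row[f"DP_{s}"] = dp
            row[f"DV_{s}"] = dv
        out.append(row)
    return pd.DataFrame(out)
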