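#!/usr/bin/env python
"""Generate one complete synthetic study dataset with known ground truth.

Writes the raw inputs every later stage consumes (bulk theta table,
mutant-panel VCF, gene models, genome, root polylines, force curves,
truth JSON) under scratch/simdata/ and a small summary under results/.
"""

from pathlib import Path

import pandas as pd

from steeproot import dataio, simulate

SEED = 20260927
OUT = Path("scratch/simdata")
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    # mapping-scale config: sequence-free, 7 x 100 Mb
    cfg = simulate.SimConfig(seed=SEED)
    thetas, truth = simulate.simulate_bsa_inputs(cfg)
    thetas.to_csv(OUT / "thetas.csv", index=False)
    counts = pd.Series(truth.phenotypes).value_counts().to_dict()
    print(f"F2 of {cfg.f2_size}: {counts} (recessive steep class)")

    # desk-scale sequencing config: 2 x 1 Mb with sequence and gene models
    seq_cfg = simulate.SimConfig(
        seed=SEED, n_chromosomes=2, chrom_length_bp=1_000_000,
        marker_spacing_bp=50_000, causal_gene=("chr1", 500_000, 502_999),
    )
    genome = simulate.simulate_genome(seq_cfg)
    genes = simulate.simulate_gene_models(seq_cfg)
    panel, panel_truth = simulate.simulate_mutant_panel(seq_cfg, genome=genome, gene_models=genes)
    dataio.write_fasta(genome, OUT / "genome.fa")
    dataio.write_gff3(genes, OUT / "genes.gff3")
    dataio.write_vcf(
        panel.drop(columns="owner"), list(seq_cfg.line_names), OUT / "panel.vcf",
        contig_lengths={c: seq_cfg.chrom_length_bp for c in seq_cfg.chromosomes},
    )
    print(f"mutant panel: {len(panel)} SNVs across {seq_cfg.n_mutant_lines} lines; "
          f"causal alleles at {panel_truth.causal_positions}")

    # phenotyping instruments
    roots = {}
    for i in range(12):
        df = simulate.simulate_root_polyline(seq_cfg.root_sim, seq_cfg.rng(f"root{i}"))
        df.attrs["root_class"] = "seminal"
        roots[f"root{i:02d}"] = df
    dataio.write_polylines(roots, OUT / "polylines.csv")
    curves = {
        f"curve{i:03d}": simulate.simulate_force_curve(seq_cfg.force_curve, seq_cfg.rng(f"curve{i}"))
        for i in range(10)
    }
    dataio.write_force_curves(curves, OUT / "force_curves.csv")

    dataio.write_json(
        {
            "seed": SEED,
            "f2_phenotype_counts": counts,
            "panel_variants": len(panel),
            "causal_positions": panel_truth.causal_positions,
        },
        RESULTS / "01_simulation_summary.json",
    )
    print(f"raw inputs in {OUT}, summary in {RESULTS/'01_simulation_summary.json'}")


if __name__ == "__main__":
    main()
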