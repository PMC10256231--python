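"""Generate the synthetic single-plant field trial used by all later steps.

Emits the raw count matrix, sample metadata, phenotype table, field layout,
height series, daily temperatures and the generative ground truth under
results/simulated_trial/.
"""

import argparse
from pathlib import Path

from fieldomics import simulate
from fieldomics.pipeline import write_simulation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-genes", type=int, default=1000)
    ap.add_argument("--n-causal", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/simulated_trial"))
    args = ap.parse_args()

    cfg = simulate.SimulationConfig(
        n_genes=args.n_genes, n_causal_genes=args.n_causal, seed=args.seed
    )
    trial = simulate.simulate_trial(cfg)
    paths = write_simulation(trial, args.out)

    design = trial["design"]
    print(f"field: {design.n_rows}x{design.n_cols} grid, "
          f"{design.analysis_mask.sum()} analysis plants")
    print(f"counts: {trial['counts'].shape[0]} genes x "
          f"{trial['counts'].shape[1]} samples")
    print(f"causal genes: {len(trial['truth'].causal_gene_ids)}")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
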