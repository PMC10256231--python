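"""Normalize the simulated counts with the batch-aware regularized-log model.

Reads the trial written by 01_simulate_trial.py, fits size factors,
repeat-based dispersions and the penalized NB model, and writes the rlog
matrix (genes x plants) plus the batch/size-factor normalized counts used
by the variability analysis.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fieldomics import rlog
from fieldomics.pipeline import read_counts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trial", type=Path, default=Path("results/simulated_trial"))
    ap.add_argument("--out", type=Path, default=Path("results/normalized"))
    args = ap.parse_args()

    counts = rlog.drop_unexpressed(read_counts(args.trial / "counts.tsv"))
    meta = pd.read_csv(args.trial / "sample_meta.csv")

    s = rlog.estimate_size_factors(counts)
    disp = rlog.estimate_dispersions(counts, s, meta=meta)
    model = rlog.fit_rlog(counts, meta, dispersions=disp, size_factors=s)
    rmat = rlog.rlog_matrix(model)
    normed = rlog.batch_normalized_counts(counts, model, meta, s)

    args.out.mkdir(parents=True, exist_ok=True)
    rmat.to_csv(args.out / "rlog.tsv", sep="\t")
    normed.to_csv(args.out / "normalized_counts.tsv", sep="\t")
    pd.DataFrame({"size_factor": s, "dispersion": disp.reindex(counts.index)}).to_csv(
        args.out / "per_gene_sample_estimates.tsv", sep="\t"
    )

    print(f"fitted {len(counts)} genes over {counts.shape[1]} samples "
          f"({len(rmat.columns)} plants after collapsing repeats)")
    print(f"global prior variance (log2 plant effects): {model.prior_variance:.3f}")
    print(f"size factors span {s.min():.2f}-{s.max():.2f}; "
          f"median dispersion {np.median(disp):.4f}")
    print(f"fallback fits: {int(model.fallback.sum())}")


if __name__ == "__main__":
    main()
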