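"""Mantel concordance of between-sample similarities.

For each group (disease, control) and each pair of layers, computes the
subject-by-subject Spearman similarity matrices over all features and
tests their concordance by permuting the sample-to-subject assignment of
one layer. Emits the 2 x 3 grid.

    python analysis/06_concordance.py [--seed 1] [--n-perm 9999]
"""
import argparse
from pathlib import Path

from triomics.concordance import pairwise_concordance
from triomics.io import read_matrix_tsv, read_subjects_tsv
from triomics.pipeline import stage_seeds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=9999)
    ap.add_argument("--sim", default="results/simulated")
    ap.add_argument("--pre", default="results/preprocessed")
    ap.add_argument("--out", default="results/concordance")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_subjects_tsv(Path(args.sim) / "subjects.tsv")
    layers = {
        layer: read_matrix_tsv(Path(args.pre) / f"{layer}_normalized.tsv", layer)
        for layer in ("serum", "pbc", "skin")
    }
    grid = pairwise_concordance(
        layers, subjects, n_perm=args.n_perm, seed=stage_seeds(args.seed)["concordance"]
    )
    grid.to_csv(out / "mantel_grid.tsv", sep="\t", index=False)
    print("Mantel concordance grid (Spearman of upper-triangle similarities):")
    for _, row in grid.iterrows():
        print(f"  {row['group']:8s} {row['layer_a']}-{row['layer_b']}: "
              f"rho={row['rho']:.3f}, p={row['p']:.4g} (n={row['n_subjects']})")


if __name__ == "__main__":
    main()
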