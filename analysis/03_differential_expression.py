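"""Differential expression per layer and serum trait association.

Fits the moderated group model (disease vs control, adjusting for age
and sex) in each layer, and the severity-score association within the
disease arm (model p plus plain and partial Spearman). Also runs the
PCA-space multivariate permutation test of group separation on the
serum panel.

    python analysis/03_differential_expression.py [--seed 1]
"""
import argparse
from pathlib import Path

from triomics.de import fit_group_de, multivariate_group_separation, trait_association
from triomics.io import read_matrix_tsv, read_subjects_tsv
from triomics.pipeline import stage_seeds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", default="results/simulated")
    ap.add_argument("--pre", default="results/preprocessed")
    ap.add_argument("--out", default="results/de")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_subjects_tsv(Path(args.sim) / "subjects.tsv")

    for layer in ("serum", "pbc", "skin"):
        mat = read_matrix_tsv(Path(args.pre) / f"{layer}_normalized.tsv", layer)
        res = fit_group_de(mat, subjects, covariates=("age", "sex"), moderate=True)
        res.to_csv(out / f"de_{layer}.tsv", sep="\t", index_label="feature_id")
        n_sig = int((res["fdr"] < 0.05).sum())
        n_up = int(((res["fdr"] < 0.05) & (res["direction"] == "up")).sum())
        print(f"{layer}: {n_sig} features at FDR<5% ({n_up} up, {n_sig - n_up} down)")

    serum = read_matrix_tsv(Path(args.pre) / "serum_normalized.tsv", "serum")
    trait = trait_association(serum, subjects, trait="mrss", covariates=("age", "sex"))
    trait.to_csv(out / "trait_association.tsv", sep="\t", index_label="feature_id")
    print(f"severity score: {int((trait['fdr'] < 0.05).sum())} serum proteins at FDR<5%")

    sep = multivariate_group_separation(
        serum, subjects["group"].reindex(serum.sample_ids),
        k_components=2, n_perm=999, seed=stage_seeds(args.seed)["de"],
    )
    print(f"multivariate group separation (PCA, k=2): T2={sep['t2']:.1f}, p={sep['p']:.4g}")


if __name__ == "__main__":
    main()
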