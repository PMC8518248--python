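"""Cross-layer comparisons of differential-expression profiles.

1. Spearman correlation between serum-protein and transcript effect
   estimates on gene-mapped pairs (serum selection: raw p < 0.05), with
   a subject-level group-relabeling permutation p — run for skin and for
   blood.
2. Sign concordance of serum disease effects with severity associations.
3. Per-gene skin-blood expression correlation within each group.

    python analysis/04_cross_layer.py [--seed 1] [--n-perm 999]
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from triomics.crosslayer import (
    disease_vs_trait_concordance,
    per_gene_cross_tissue_correlation,
    permutation_effect_correlation,
)
from triomics.io import read_feature_map_tsv, read_matrix_tsv, read_subjects_tsv
from triomics.pipeline import stage_seeds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--sim", default="results/simulated")
    ap.add_argument("--pre", default="results/preprocessed")
    ap.add_argument("--de", default="results/de")
    ap.add_argument("--out", default="results/cross_layer")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_subjects_tsv(Path(args.sim) / "subjects.tsv")
    fmap = read_feature_map_tsv(Path(args.sim) / "feature_map.tsv")
    serum = read_matrix_tsv(Path(args.pre) / "serum_normalized.tsv", "serum")
    seed = stage_seeds(args.seed)["crosslayer"]

    summary = {}
    for layer in ("skin", "pbc"):
        mat = read_matrix_tsv(Path(args.pre) / f"{layer}_normalized.tsv", layer)
        pairs = pd.read_csv(Path(args.pre) / f"pairs_serum_{layer}.tsv", sep="\t")
        res = permutation_effect_correlation(
            serum, mat, subjects, pairs, selection="p:0.05",
            n_perm=args.n_perm, seed=seed,
        )
        summary[layer] = {"rho": res.rho_obs, "p_perm": res.p_perm, "n_pairs": res.n_pairs}
        print(f"serum-{layer} effect correlation: rho={res.rho_obs:.3f}, "
              f"permutation p={res.p_perm:.4g} over {res.n_pairs} pairs")

    de_serum = pd.read_csv(Path(args.de) / "de_serum.tsv", sep="\t", index_col=0)
    trait = pd.read_csv(Path(args.de) / "trait_association.tsv", sep="\t", index_col=0)
    conc = disease_vs_trait_concordance(de_serum, trait, cutoff=0.05)
    summary["disease_trait"] = {
        "n_tested": conc.n_tested, "n_concordant": conc.n_concordant, "rho": conc.rho
    }
    print(f"disease vs severity concordance: {conc.n_concordant}/{conc.n_tested} "
          f"sign-concordant among FDR<5% hits; effect-slope Spearman rho={conc.rho:.3f}")

    skin = read_matrix_tsv(Path(args.pre) / "skin_normalized.tsv", "skin")
    pbc = read_matrix_tsv(Path(args.pre) / "pbc_normalized.tsv", "pbc")
    per_gene = per_gene_cross_tissue_correlation(skin, pbc, fmap, subjects)
    per_gene.to_csv(out / "gene_cross_tissue.tsv", sep="\t", index=False)
    sig = per_gene[per_gene["fdr"] < 0.05]
    print(f"skin-blood per-gene correlation: {sig['gene_id'].nunique()} genes at FDR<5% "
          f"in at least one group; {int(per_gene['discordant'].sum() // 2)} direction-discordant")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
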