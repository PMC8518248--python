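"""Generate the default synthetic three-layer cohort and write its raw
tables.

Produces a clinical table (49 disease / 25 control subjects), a
981-protein serum panel with per-protein LLODs and 70 heavily censored
analytes, two 1,500-probe transcript layers with detection p-values, the
feature-to-gene map, and the planted truth record. Run from the
repository root:

    python analysis/01_simulate.py [--seed 1] [--out results/simulated]
"""
import argparse
import json
from pathlib import Path

from triomics import SyntheticConfig
from triomics.io import write_feature_map_tsv, write_matrix_tsv, write_subjects_tsv
from triomics.pipeline import stage_seeds
from triomics.simulate import generate_cohort, generate_multiomic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/simulated")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=stage_seeds(args.seed)["simulate"])
    subjects = generate_cohort(cfg)
    serum, llod, pbc, pbc_det, skin, skin_det, fmap, truth = generate_multiomic(subjects, cfg)

    write_subjects_tsv(subjects, out / "subjects.tsv")
    for name, mat in (("serum", serum), ("pbc", pbc), ("skin", skin)):
        write_matrix_tsv(mat, out / f"{name}_raw.tsv")
    llod.rename("llod").to_csv(out / "serum_llod.tsv", sep="\t", index_label="feature_id")
    pbc_det.to_csv(out / "pbc_detection_p.tsv", sep="\t", index_label="feature_id")
    skin_det.to_csv(out / "skin_detection_p.tsv", sep="\t", index_label="feature_id")
    write_feature_map_tsv(fmap, out / "feature_map.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)

    n_d = (subjects["group"] == "disease").sum()
    print(f"cohort: {n_d} disease / {len(subjects) - n_d} control subjects")
    print(f"serum panel: {serum.shape[0]} proteins x {serum.shape[1]} samples "
          f"({len(truth.censored_proteins)} designated heavily censored)")
    print(f"transcript layers: pbc {pbc.shape[0]} probes, skin {skin.shape[0]} probes")
    print(f"planted differential features: "
          f"{ {k: len(v) for k, v in truth.de_features.items()} }")
    print(f"wrote raw tables to {out}/")


if __name__ == "__main__":
    main()
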