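"""Preprocess the simulated layers the way the study preprocessed its
cohort data.

Serum: analytes with more than half their observations below the LLOD
are excluded (the exclusion pattern is checked for disease/control
imbalance), remaining sub-LLOD values are replaced by the LLOD.
Transcripts: probes are kept when their average detection p-value is
below 0.01. All layers are then quantile normalized (the simulated
values are already on the log2 scale). Reads 01's output:

    python analysis/02_preprocess.py [--in results/simulated] [--out results/preprocessed]
"""
import argparse
from pathlib import Path

import pandas as pd

from triomics.io import (
    read_feature_map_tsv,
    read_matrix_tsv,
    read_subjects_tsv,
    write_matrix_tsv,
)
from triomics.preprocess import (
    filter_by_detection,
    filter_by_llod,
    impute_llod,
    log2_quantile_normalize,
    map_features,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", default="results/simulated")
    ap.add_argument("--out", default="results/preprocessed")
    args = ap.parse_args()

    ind, out = Path(args.indir), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_subjects_tsv(ind / "subjects.tsv")
    fmap = read_feature_map_tsv(ind / "feature_map.tsv")

    serum_raw = read_matrix_tsv(ind / "serum_raw.tsv", "serum")
    llod = pd.read_csv(ind / "serum_llod.tsv", sep="\t", index_col=0)["llod"]
    kept, report = filter_by_llod(
        serum_raw, llod, subjects["group"].reindex(serum_raw.sample_ids)
    )
    serum = log2_quantile_normalize(impute_llod(kept, llod), log_transform=False)
    print(f"serum: {serum_raw.shape[0]} assayed -> {serum.shape[0]} retained "
          f"({report.n_excluded} excluded for >50% below LLOD)")
    imb = report.table.loc[report.table["excluded"], "imbalance_fdr"]
    print(f"  censoring imbalance: {int((imb < 0.05).sum())} of {len(imb)} excluded "
          "analytes show disease/control imbalance at FDR<5%")

    layers = {"serum": serum}
    for layer in ("pbc", "skin"):
        raw = read_matrix_tsv(ind / f"{layer}_raw.tsv", layer)
        det = pd.read_csv(ind / f"{layer}_detection_p.tsv", sep="\t", index_col=0)
        filt = filter_by_detection(raw, det, threshold=0.01)
        norm = log2_quantile_normalize(filt, log_transform=False)
        layers[layer] = norm
        print(f"{layer}: {raw.shape[0]} probes -> {norm.shape[0]} detected (mean "
              "detection p < 0.01), quantile normalized")

    for name, mat in layers.items():
        write_matrix_tsv(mat, out / f"{name}_normalized.tsv")
    report.table.to_csv(out / "llod_report.tsv", sep="\t", index_label="feature_id")

    for layer in ("pbc", "skin"):
        pairs = map_features(fmap, layers["serum"], layers[layer])
        pairs.to_csv(out / f"pairs_serum_{layer}.tsv", sep="\t", index=False)
        print(f"protein-transcript pairs via shared genes, serum-{layer}: {len(pairs)}")


if __name__ == "__main__":
    main()
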