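#!/usr/bin/env python
"""Extract the classical morphological feature table from stain crops (the
hand-crafted comparator to the learned latents) and run feature selection."""

import argparse
from pathlib import Path

import numpy as np

from stvae.features import extract_classical_features, select_features
from stvae.preprocess import extract_stain_crop
from stvae.synthetic import load_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data/recovery"))
    ap.add_argument("--crop-size", type=int, default=64)
    ap.add_argument("--out", type=Path, default=Path("results/features"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = load_dataset(args.data)
    ids = ds.cells["cell"].to_numpy()
    crops = np.stack([extract_stain_crop(ds, int(c), args.crop_size).tensor
                      for c in ids])
    table = extract_classical_features(crops, cell_ids=ids)
    selected = select_features(table)
    selected.values.to_csv(args.out / f"classical_{args.crop_size}px.csv")
    print(f"extracted {table.values.shape[1]} features, "
          f"{selected.values.shape[1]} kept after selection "
          f"-> {args.out / f'classical_{args.crop_size}px.csv'}")


if __name__ == "__main__":
    main()
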