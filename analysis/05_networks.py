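#!/usr/bin/env python
"""Thresholded Spearman correlation networks between taxa and metabolites.

Keeps edges with |rho| > 0.5 and p < 0.05 between the filtered taxa table
and each metabolome, plus a taxa ordination for context. Writes
results/network_taxa_*.tsv (source, target, rho, p) and
results/pcoa_taxa.tsv.
"""

import argparse
import importlib.util
import warnings
from pathlib import Path

from omixplain.association import build_correlation_network
from omixplain.similarity import bray_curtis, pcoa

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "explainability_driver", ROOT / "analysis" / "02_explainability.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_filtered_layers = _mod.load_filtered_layers


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--r-threshold", type=float, default=0.5)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phen, layers = load_filtered_layers(args.cohort)

        ord_ = pcoa(bray_curtis(layers["taxa"]), k=2)
        coords = ord_.coordinates.copy()
        coords["group"] = phen.group
        coords.to_csv(args.out_dir / "pcoa_taxa.tsv", sep="\t", index_label="sample_id")
        print("taxa PCoA: axis 1/2 explain "
              f"{100 * ord_.proportion_explained[0]:.1f}% / "
              f"{100 * ord_.proportion_explained[1]:.1f}%")

        for kind in ("rumen_metabolome", "serum_metabolome"):
            edges = build_correlation_network(
                layers["taxa"], layers[kind], r_threshold=args.r_threshold, alpha=0.05
            )
            out = args.out_dir / f"network_taxa_{kind}.tsv"
            edges.to_csv(out, sep="\t", index=False)
            pos = (edges["rho"] > 0).sum()
            print(f"taxa-{kind}: {len(edges)} edges "
                  f"({pos} positive, {len(edges) - pos} negative) -> {out}")


if __name__ == "__main__":
    main()
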