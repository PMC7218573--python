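#!/usr/bin/env python
"""Screen MPY-associated metabotypes and their microbiome responsiveness.

Spearman-screens every rumen and serum metabolite against MPY (raw
p < 0.05 defines a metabotype, signed by the correlation direction), then
tests each rumen metabotype as a continuous covariate in a PERMANOVA on
the taxa Bray-Curtis distance matrix; BH FDR < 0.05 across the tested
metabotypes flags the microbiome-responsive ones. Writes
results/metabotypes_{rumen,serum}_metabolome.tsv.
"""

import argparse
import warnings
from pathlib import Path

import importlib.util

from omixplain.association import (
    assess_microbiome_responsiveness,
    metabotype_frame,
    screen_metabotypes,
)
from omixplain.similarity import bray_curtis

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
    parser.add_argument("--n-perm", type=int, default=999)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phen, layers = load_filtered_layers(args.cohort)
        taxa_dist = bray_curtis(layers["taxa"])
        for kind in ("rumen_metabolome", "serum_metabolome"):
            results = screen_metabotypes(layers[kind], phen, alpha=0.05)
            if kind == "rumen_metabolome":
                results = assess_microbiome_responsiveness(
                    results, layers[kind], taxa_dist,
                    n_perm=args.n_perm, seed=args.seed,
                )
            frame = metabotype_frame(results)
            out = args.out_dir / f"metabotypes_{kind}.tsv"
            out.parent.mkdir(parents=True, exist_ok=True)
            frame.to_csv(out, sep="\t")
            pos = (frame["sign_class"] == "MPY-positive").sum()
            neg = (frame["sign_class"] == "MPY-negative").sum()
            resp = frame["microbiome_responsive"].sum()
            print(f"{kind}: {pos} MPY-positive + {neg} MPY-negative metabotypes"
                  + (f"; {resp} microbiome-responsive" if kind == "rumen_metabolome" else ""))
            print(f"  -> {out}")


if __name__ == "__main__":
    main()
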