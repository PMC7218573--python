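#!/usr/bin/env python
"""Differential features between the HH and LL groups.

Taxa: Wilcoxon rank-sum + BH FDR, and the LEfSe-style score (significant
when p < 0.05 and LDA score > 2). Functions: LEfSe-style score.
Metabolites: Welch t-test + BH FDR combined with PLS-DA VIP > 1. Writes
one results/differential_*.tsv per procedure.
"""

import argparse
import importlib.util
import warnings
from pathlib import Path

from omixplain.differential import (
    differential_metabolites,
    lefse_style_score,
    wilcoxon_differential,
)

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
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phen, layers = load_filtered_layers(args.cohort)
        groups = phen.group

        wil = wilcoxon_differential(layers["taxa"], groups)
        wil.to_csv(args.out_dir / "differential_taxa_wilcoxon.tsv", sep="\t")
        print(f"taxa Wilcoxon+FDR: {int(wil['significant'].sum())} significant"
              f" of {len(wil)}")

        for kind in ("taxa", "function"):
            lefse = lefse_style_score(layers[kind], groups)
            lefse.to_csv(args.out_dir / f"differential_{kind}_lefse.tsv", sep="\t")
            sig = lefse[lefse["significant"]]
            hh = (sig["effect_direction"] == "HH").sum()
            print(f"{kind} LEfSe-style: {len(sig)} significant "
                  f"({hh} HH-enriched, {len(sig) - hh} LL-enriched)")

        for kind in ("rumen_metabolome", "serum_metabolome"):
            diff = differential_metabolites(layers[kind], groups)
            diff.to_csv(args.out_dir / f"differential_{kind}.tsv", sep="\t")
            sig = diff[diff["significant"]]
            print(f"{kind} t-test+VIP: {len(sig)} significant of {len(diff)}")


if __name__ == "__main__":
    main()
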