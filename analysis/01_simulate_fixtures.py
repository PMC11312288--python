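#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the study design: a two-condition (WT vs AQP4-KO) log2 expression
matrix with 3 pooled samples per condition and planted marker folds
(Spp1 at 600-fold, Gpnmb, Itgax, Cd68, Atp6v0d2, ... at lower folds, plus
background up/down genes), a block-correlated collection of 11 microglial
population signatures, a triplicate 18S-normalised qPCR Ct plate, and a
gene-set collection (planted microglial set + random sets).

Writes results/analysis/data/ and prints where each file went.
"""
from pathlib import Path

from microsig.pipeline import AnalysisConfig, write_fixture_bundle

OUT = Path("results/analysis")


def main() -> None:
    cfg = AnalysisConfig(seed=11, out_dir=str(OUT))
    paths = write_fixture_bundle(cfg, OUT / "data")
    print("Synthetic study inputs (seed 11):")
    for name, p in paths.items():
        print(f"  {name:11s} -> {p}")


if __name__ == "__main__":
    main()
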