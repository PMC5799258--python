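"""Community comparison: Bray-Curtis PERMANOVA, NMDS ordination, UPGMA.

Tests whether host type structures the microbiome (one-way PERMANOVA on
host over all samples and on location within each host), runs all pairwise
host-by-location group comparisons, and summarizes the 2-D NMDS fit.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coralmicro.pipeline import run_pipeline

import importlib.util as _iu
_spec = _iu.spec_from_file_location("sim", Path(__file__).parent / "01_simulate.py")
_sim = _iu.module_from_spec(_spec)
_spec.loader.exec_module(_sim)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = _sim.config(args.seed)
    run_pipeline(cfg, stages=("simulate", "beta"))
    outdir = Path(cfg.outdir)

    perm = pd.read_csv(outdir / "permanova.tsv", sep="\t")
    host = perm[perm.factor == "host"].iloc[0]
    print(f"host effect: pseudo-F = {host.pseudo_F:.2f}, "
          f"P = {host.p_value:.3f} ({host.n_permutations} permutations)")
    for factor in ("location|Galaxea", "location|Montipora"):
        row = perm[perm.factor == factor].iloc[0]
        print(f"{factor}: pseudo-F = {row.pseudo_F:.2f}, P = {row.p_value:.3f}")
    pairwise = perm[perm.factor.str.contains("-vs-")]
    sig = (pairwise.p_value < 0.05).sum()
    print(f"pairwise group tests: {sig}/{len(pairwise)} significant at "
          f"P < 0.05 (raw p-values)")

    stress = json.loads((outdir / "nmds_stats.json").read_text())["stress"]
    print(f"NMDS 2-D stress = {stress:.3f} -> {outdir/'nmds.tsv'}")
    print(f"UPGMA dendrogram -> {outdir/'dendrogram.nwk'}")


if __name__ == "__main__":
    main()
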