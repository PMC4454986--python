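#!/usr/bin/env python
"""Collate predicted concentrations across archetypes into one table.

Reads the per-archetype concentration summaries from step 02 and writes a
single long-format CSV (``results/concentrations_all.csv``) with modal
value and 95% range per compartment, basis and archetype — the synthetic
analog of a mode/95%-interval concentration table, all values rounded to
two significant digits.  Prints the most exposed compartment per
archetype.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--runs", type=Path, default=Path("results/runs"))
    ap.add_argument("--out", type=Path, default=Path("results/concentrations_all.csv"))
    args = ap.parse_args()

    frames = []
    for run_dir in sorted(args.runs.iterdir()):
        f = run_dir / "concentrations.csv"
        if not f.exists():
            continue
        df = pd.read_csv(f)
        df.insert(0, "archetype", run_dir.name)
        frames.append(df)
    if not frames:
        raise SystemExit(f"no run outputs under {args.runs}; run step 02 first")
    allc = pd.concat(frames, ignore_index=True)
    allc.to_csv(args.out, index=False)
    print(f"wrote {args.out} ({len(allc)} rows)\n")

    # technical wastewater compartments are directly comparable across
    # archetypes (same units); print them as the narrative headline
    for archetype, grp in allc.groupby("archetype"):
        g = grp.set_index(["compartment", "basis"])
        for cid, label in (("effluent", "STP effluent"), ("sludge", "sewage sludge")):
            row = g.loc[(cid, "annual_flowthrough")]
            print(
                f"{archetype:<24} {label:<13} mode {row['mode']:>8g} {row['unit']}"
                f"  (95% range {row['q025']:g}-{row['q975']:g})"
            )


if __name__ == "__main__":
    main()
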