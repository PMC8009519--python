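#!/usr/bin/env python
"""Tabulate the simulated system compositions.

For each (concentration, box, solvent) condition of the study design this
reproduces the surfactant molecule count from the molarity and the solvent
bead count from the bulk-density fill rule, and writes the table to
results/compositions.csv.
"""

from pathlib import Path

import pandas as pd

from hpfsurf import molecule_count, solvent_count

CONDITIONS = [
    (1, 28, "W"), (2, 28, "W"), (5, 28, "W"), (10, 28, "W"), (15, 28, "W"),
    (50, 28, "W"), (100, 28, "W"), (200, 28, "W"), (200, 14, "C"),
]


def main() -> None:
    rows = []
    for conc, box, solvent in CONDITIONS:
        n = molecule_count(conc, box)
        rows.append({
            "concentration_mM": conc,
            "box_nm": box,
            "solvent": {"W": "water", "C": "cyclohexane"}[solvent],
            "surfactant_molecules": n,
            "solvent_beads": solvent_count(box, n, solvent),
        })
    df = pd.DataFrame(rows)
    out = Path("results")
    out.mkdir(exist_ok=True)
    df.to_csv(out / "compositions.csv", index=False)
    print(df.to_string(index=False))
    print("\nwrote results/compositions.csv")


if __name__ == "__main__":
    main()
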