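#!/usr/bin/env python
"""Reagent dosimetry tables: per-cell doses, BCA calibration, mass balance.

Reproduces the dose arithmetic behind the delivery comparison: the per-cell
sgRNA doses of the two lipofection plate formats, the 1:2:5 magnetofection
dose series, the BCA standard-curve fit (slope ~0.0092 absorbance per
ug/mL), and the immobilization mass balance of the two RNP constructs.

Writes results/05_doses.csv, 05_bca_calibration.json and 05_mass_balance.csv.
"""

from pathlib import Path

import pandas as pd

from rnptrack.dosimetry import (
    DoseSpec,
    concentration_from_absorbance,
    dose_per_cell,
    fit_linear_calibration,
    immobilization_balance,
    round_sig,
)

LIPOFECTION = [
    ("96-well, 75 uL", DoseSpec(volume=75, concentration=25, cells=20_000)),
    ("96-well, 50 uL", DoseSpec(volume=50, concentration=25, cells=20_000)),
    ("24-well, 75 uL", DoseSpec(volume=75, concentration=25, cells=100_000)),
    ("24-well, 50 uL", DoseSpec(volume=50, concentration=25, cells=100_000)),
]

# magnetofection: printed anchor 0.41 ng/cell at 100 uL on 1e5 cells
MAGNETO_CONC = 0.41 * 100_000 / 100  # ng/uL implied by the anchor
MAGNETO_VOLUMES = (100, 200, 500)

# BCA standards: the published concentrations with absorbances on the
# printed regression line (slope 0.0092, intercept ~0)
BCA_CONCENTRATIONS = (0.0, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0)

BALANCES = [("DLB-1 construct", 100.0, 42.90),
            ("SaB-1 construct", 100.0, 38.68)]


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "results"
    out.mkdir(exist_ok=True)

    rows = [{"condition": name,
             "volume_uL": spec.volume, "conc_ng_uL": spec.concentration,
             "cells": spec.cells,
             "dose_ng_per_cell": round_sig(dose_per_cell(spec), 2)}
            for name, spec in LIPOFECTION]
    for volume in MAGNETO_VOLUMES:
        spec = DoseSpec(volume=volume, concentration=MAGNETO_CONC,
                        cells=100_000)
        rows.append({"condition": f"magnetofection, {volume} uL",
                     "volume_uL": volume, "conc_ng_uL": MAGNETO_CONC,
                     "cells": spec.cells,
                     "dose_ng_per_cell": round(dose_per_cell(spec), 2)})
    doses = pd.DataFrame(rows)
    print(doses.to_string(index=False))
    doses.to_csv(out / "05_doses.csv", index=False)

    cal = fit_linear_calibration(
        [(c, 0.0092 * c) for c in BCA_CONCENTRATIONS])
    check = concentration_from_absorbance(0.92, cal)
    print(f"\nBCA calibration: slope = {cal.slope:.4f} /(ug/mL), "
          f"intercept = {cal.intercept:.2e}, r^2 = {cal.r_squared:.3f}; "
          f"A = 0.92 -> {check:.1f} ug/mL")
    (out / "05_bca_calibration.json").write_text(
        f'{{"slope": {cal.slope}, "intercept": {cal.intercept}, '
        f'"r_squared": {cal.r_squared}}}\n')

    balance_rows = []
    for name, loaded, bound in BALANCES:
        mb = immobilization_balance(loaded, bound)
        balance_rows.append({
            "construct": name, "loaded_ug": mb.loaded, "bound_ug": mb.bound,
            "unbound_ug": round(mb.unbound, 2),
            "efficiency_percent": round(mb.efficiency, 2)})
        print(f"{name}: {mb.efficiency:.2f}% immobilized, "
              f"{mb.unbound:.2f} ug unbound")
    pd.DataFrame(balance_rows).to_csv(out / "05_mass_balance.csv", index=False)
    print(f"wrote tables under {out}")


if __name__ == "__main__":
    main()
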