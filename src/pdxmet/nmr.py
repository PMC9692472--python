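"""Steady-state NMR metabolite quantification and fractional enrichment.

Absolute concentrations come from 1-D peak areas referenced to the TSP
internal standard (9 equivalent protons), corrected for proton
multiplicity and normalized to tissue mass:

    conc [nmol/mg] = (area / TSP area) * (TSP protons / metabolite protons)
                     * TSP amount [nmol] / tissue mass [mg]

Relative concentrations (RU) are simple ratios of cross-peak volume to the
TSP reference, with no proton correction. Fractional enrichment is the
HSQC-derived labeled concentration divided by the total:
FE = [13C-labeled]/[total], flagged above 1.02 (noise allowance).

The isotopomer flux modeling lives in :mod:`pdxmet.isotopomer`; this
module assembles the per-metabolite table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "absolute_concentration",
    "relative_concentration",
    "fractional_enrichment",
    "quantify_1d",
    "add_fractional_enrichment",
    "FE_FLAG_THRESHOLD",
]

FE_FLAG_THRESHOLD = 1.02


def absolute_concentration(area: float, tsp_area: float, protons: int,
                           tsp_amount_nmol: float, tissue_mass_mg: float,
                           tsp_protons: int = 9) -> float:
    """Absolute metabolite concentration in nmol per mg tissue."""
    if tsp_area <= 0:
        raise ValueError("TSP area must be positive")
    if tissue_mass_mg <= 0:
        raise ValueError("tissue mass must be positive")
    if protons <= 0 or tsp_protons <= 0:
        raise ValueError("proton counts must be positive")
    if area < 0:
        raise ValueError("peak area must be non-negative")
    return (area / tsp_area) * (tsp_protons / protons) * tsp_amount_nmol / tissue_mass_mg


def relative_concentration(volume: float, tsp_reference: float) -> float:
    """Concentration relative to TSP (RU): a plain ratio, no proton correction."""
    if tsp_reference <= 0:
        raise ValueError("TSP reference must be positive")
    if volume < 0:
        raise ValueError("peak volume must be non-negative")
    return volume / tsp_reference


def fractional_enrichment(labeled: float, total: float) -> float:
    """FE = labeled / total concentration. NaN (undefined) when total is 0."""
    if labeled < 0 or total < 0:
        raise ValueError("concentrations must be non-negative")
    if total == 0:
        return np.nan
    return labeled / total


def quantify_1d(peaks_1d: pd.DataFrame, tsp_amount_nmol: float,
                tissue_mass_mg: float, tsp_name: str = "TSP",
                tsp_protons: int = 9) -> pd.DataFrame:
    """Build the metabolite table from a 1-D peak-area table.

    ``peaks_1d`` needs columns ``metabolite``, ``area``, ``protons`` and a
    TSP row supplying the reference area. Returns one row per metabolite
    with absolute (nmol/mg) and TSP-relative (RU) concentrations.
    """
    for col in ("metabolite", "area", "protons"):
        if col not in peaks_1d.columns:
            raise ValueError(f"peak table missing column {col!r}")
    tsp_rows = peaks_1d[peaks_1d["metabolite"] == tsp_name]
    if len(tsp_rows) != 1:
        raise ValueError(f"expected exactly one {tsp_name} row")
    tsp_area = float(tsp_rows["area"].iloc[0])
    if tsp_area <= 0:
        raise ValueError("TSP area must be positive")

    rows = []
    for _, r in peaks_1d[peaks_1d["metabolite"] != tsp_name].iterrows():
        rows.append({
            "metabolite": r["metabolite"],
            "area": float(r["area"]),
            "protons": int(r["protons"]),
            "absolute_nmol_mg": absolute_concentration(
                float(r["area"]), tsp_area, int(r["protons"]),
                tsp_amount_nmol, tissue_mass_mg, tsp_protons),
            "relative_ru": relative_concentration(float(r["area"]), tsp_area),
        })
    return pd.DataFrame(rows)


def add_fractional_enrichment(table: pd.DataFrame,
                              hsqc: pd.DataFrame) -> pd.DataFrame:
    """Join HSQC labeled concentrations and compute FE per metabolite.

    Metabolites absent from the HSQC table get labeled concentration 0
    (no detectable label). FE values above 1.02 are flagged, not clipped.
    """
    if "labeled_nmol_mg" not in hsqc.columns:
        raise ValueError("HSQC table missing column 'labeled_nmol_mg'")
    out = table.merge(hsqc[["metabolite", "labeled_nmol_mg"]],
                      on="metabolite", how="left")
    out["labeled_nmol_mg"] = out["labeled_nmol_mg"].fillna(0.0)
    out["fe"] = [
        fractional_enrichment(lab, tot)
        for lab, tot in zip(out["labeled_nmol_mg"], out["absolute_nmol_mg"])
    ]
    out["fe_flagged"] = out["fe"] > FE_FLAG_THRESHOLD
    return out
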