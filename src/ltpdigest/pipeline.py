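"""Table-level orchestration: from TSV inputs to report tables.

These functions connect the typed single-series operations to the tabular
formats the pipeline exchanges (identification, densitometry and ELISA TSVs),
and are what both the command-line interface and the reproduction script
drive.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import DisulphideTopology, Epitope, ProteinIsoform
from .digest import CleavageRule, DEFAULT_RULES, predict_cleavage_sites
from .elisa import InhibitionCurve, fit_4pl
from .kinetics import TimeCourse, fit_decay, fit_transient, resistance_test
from .mapping import (
    IdentifiedPeptide,
    cleavage_site_usage,
    coverage,
    epitope_status,
    filter_identifications,
    map_peptides,
)


def _parse_mods(cell) -> tuple[tuple[int, str], ...]:
    if not isinstance(cell, str) or not cell:
        return ()
    out = []
    for item in cell.split(";"):
        pos, name = item.split(":", 1)
        out.append((int(pos), name))
    return tuple(out)


def identifications_to_peptides(table: pd.DataFrame) -> list[IdentifiedPeptide]:
    return [
        IdentifiedPeptide(
            sequence=row.sequence,
            spectral_count=int(row.spectral_count),
            score=float(row.score),
            sample_id=str(row.sample_id),
            reduced=bool(row.reduced),
            mods=_parse_mods(getattr(row, "mods", "")),
        )
        for row in table.itertuples(index=False)
    ]


def analyze_identifications(
    table: pd.DataFrame,
    isoform: ProteinIsoform,
    epitopes: list[Epitope],
    topology: DisulphideTopology,
    rules: tuple[CleavageRule, ...] = DEFAULT_RULES,
    min_score: float = 5.0,
    equivalence: str = "exact",
) -> dict:
    """Filter, map and summarise an identification table against one isoform.

    Returns a dict of report tables: locations, coverage map, cleavage-site
    usage, abundance matrix, epitope statuses and the unmapped peptides.
    The epitope classification uses both the cut events evidenced by peptide
    termini and the predicted specific cleavage sites of the active rules.
    """
    filtered = filter_identifications(table, min_score=min_score)
    peptides = identifications_to_peptides(filtered)
    locations, unmapped = map_peptides(peptides, [isoform], equivalence=equivalence)

    cov = coverage(locations, isoform)
    predicted = [
        s for rule in rules for s in predict_cleavage_sites(isoform, rule)
    ]
    usage = cleavage_site_usage(locations, predicted, isoform)
    observed_cuts = set(usage["position"]) | {s.position for s in predicted}
    epitope_rows = [
        {
            "epitope": epi.label,
            "status": epitope_status(epi, locations, observed_cuts),
        }
        for epi in epitopes
    ]

    loc_rows = pd.DataFrame(
        [
            {
                "accession": loc.accession,
                "start": loc.start,
                "end": loc.end,
                "sequence": loc.peptide.sequence,
                "sample_id": loc.peptide.sample_id,
                "reduced": loc.peptide.reduced,
                "spectral_count": loc.peptide.spectral_count,
                "unique_to_isoform": loc.unique_to_isoform,
                "il_ambiguous": loc.il_ambiguous,
            }
            for loc in locations
        ]
    )
    return {
        "locations": loc_rows,
        "coverage": cov,
        "usage": usage,
        "epitopes": pd.DataFrame(epitope_rows),
        "unmapped": pd.DataFrame([{"sequence": p.sequence} for p in unmapped]),
        "n_filtered_out": len(table) - len(filtered),
    }


def analyze_timecourse_table(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit every (condition, band) series in a densitometry table.

    Parent bands pass through the resistance gate (control vs final time)
    before decay fitting; fragment bands are fitted with the transient /
    rising model.  Output mirrors a rate-constant/half-life summary table.
    """
    rows = []
    for (cond, band), grp in table.groupby(["condition_id", "band"], sort=True):
        t = grp["time_min"].to_numpy(float)
        y = grp["rel_intensity"].to_numpy(float)
        tc = TimeCourse(t, y, band=band)
        if band == "parent":
            t0, t_end = t.min(), t.max()
            p, resistant = resistance_test(
                y[t == t0], y[t == t_end], alpha=alpha
            )
            if resistant:
                rows.append(
                    {
                        "condition_id": cond, "band": band, "K": math.nan,
                        "t_half_min": math.inf, "rse": math.nan,
                        "classification": "resistant", "p_resistance": p,
                    }
                )
                continue
            fit = fit_decay(tc)
            rows.append(
                {
                    "condition_id": cond, "band": band, "K": fit.K,
                    "t_half_min": fit.t_half, "rse": fit.rse,
                    "classification": "decay", "p_resistance": p,
                }
            )
        else:
            tfit = fit_transient(tc)
            rows.append(
                {
                    "condition_id": cond, "band": band, "K": tfit.k_form,
                    "t_half_min": math.nan, "rse": tfit.rse,
                    "classification": tfit.classification,
                    "p_resistance": math.nan,
                }
            )
    return pd.DataFrame(rows)


def analyze_elisa_table(table: pd.DataFrame) -> pd.DataFrame:
    """4PL-fit every (patient, sample) inhibition curve; IC50 with censoring."""
    rows = []
    for (patient, sample), grp in table.groupby(["patient_id", "sample"], sort=True):
        curve = InhibitionCurve(
            grp["conc_ug_per_ml"].to_numpy(float),
            grp["A450"].to_numpy(float),
            patient_id=patient,
            sample=sample,
        )
        fit = fit_4pl(curve)
        rows.append(
            {
                "patient_id": patient,
                "sample": sample,
                "ic50_ug_per_ml": fit.ic50.value,
                "censor": fit.ic50.censor,
                "approximate": fit.ic50.approximate,
                "ic50_display": str(fit.ic50),
                "rse": fit.rse,
            }
        )
    return pd.DataFrame(rows)


def coverage_to_bed(cov, accession: str | None = None) -> pd.DataFrame:
    """Covered intervals as BED-like half-open rows (accession, start-1, end)."""
    acc = accession or cov.accession
    return pd.DataFrame(
        [
            {"accession": acc, "start": s - 1, "end": e}
            for s, e in cov.covered_intervals()
        ]
    )
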