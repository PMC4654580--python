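"""Derived metrics and rule-based clinical calls per biopsy and per case.

The rules, with their numeric conventions:

* lymphoplasmacytic density = CD3 + CD20 + CD138 densities (cells/mm^2);
* plasma cell ratio = 100 * CD138 / (CD3 + CD20 + CD138), undefined (NaN)
  when the denominator is zero;
* inflammation: a biopsy is "inflamed" when its lymphoplasmacytic density
  is at or above the cutoff (default 200 cells/mm^2; the boundary itself
  counts as inflamed);
* light-chain restriction: kappa:lambda ratio strictly above 5.5 or
  strictly below 0.7, provided the total light-chain-positive density
  strictly exceeds 50 cells/mm^2; a biopsy not evaluable for ISH yields a
  ``not_evaluable`` call regardless of densities;
* case level: positive if any evaluable biopsy is restricted; negative if
  at least one biopsy is evaluable and none restricted; not evaluable only
  when every biopsy is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from cystiquant.config import (
    DEFAULT_DENSITY_FLOOR,
    DEFAULT_INFLAMMATION_CUTOFF,
    DEFAULT_RATIO_HIGH,
    DEFAULT_RATIO_LOW,
)


@dataclass(frozen=True)
class InflammationCall:
    lymphoplasmacytic_density: float
    call: str  # "normal" | "inflamed"
    cutoff: float = DEFAULT_INFLAMMATION_CUTOFF


@dataclass(frozen=True)
class LightChainCall:
    kl_ratio: float  # may be inf; NaN when both chains are zero
    restricted_side: str  # "kappa" | "lambda" | "none"
    call: str  # "restricted" | "polytypic" | "not_evaluable"
    ratio_bounds: tuple[float, float] = (DEFAULT_RATIO_LOW, DEFAULT_RATIO_HIGH)
    density_floor: float = DEFAULT_DENSITY_FLOOR


@dataclass(frozen=True)
class CaseSummary:
    case_id: str
    group: str
    biopsy_light_chain: dict[str, LightChainCall]
    biopsy_inflammation: dict[str, InflammationCall]
    case_light_chain: str  # "positive" | "negative" | "not_evaluable"
    case_inflamed: bool


def lymphoplasmacytic_density(d_cd3: float, d_cd20: float, d_cd138: float) -> float:
    """Total density of T cells, B cells and plasma cells, cells/mm^2."""
    for d in (d_cd3, d_cd20, d_cd138):
        if d < 0:
            raise ValueError("densities must be >= 0")
    return d_cd3 + d_cd20 + d_cd138


def plasma_cell_ratio(d_cd3: float, d_cd20: float, d_cd138: float) -> float:
    """CD138-positive percent of lymphoplasmacytic cells; NaN if none."""
    total = lymphoplasmacytic_density(d_cd3, d_cd20, d_cd138)
    if total == 0:
        return math.nan
    return 100.0 * d_cd138 / total


def classify_inflammation(
    density: float, cutoff: float = DEFAULT_INFLAMMATION_CUTOFF
) -> InflammationCall:
    """Inflamed iff density >= cutoff (inclusive boundary)."""
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    call = "inflamed" if density >= cutoff else "normal"
    return InflammationCall(
        lymphoplasmacytic_density=density, call=call, cutoff=cutoff
    )


def light_chain_call(
    d_kappa: float,
    d_lambda: float,
    ish_evaluable: bool = True,
    ratio_low: float = DEFAULT_RATIO_LOW,
    ratio_high: float = DEFAULT_RATIO_HIGH,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
) -> LightChainCall:
    """Apply the kappa:lambda restriction rule to one biopsy.

    The ratio is kappa/lambda, +inf when lambda is 0 and kappa > 0, and NaN
    (treated as polytypic) when both are 0.  A restricted call requires the
    ratio strictly outside [ratio_low, ratio_high] *and* total light-chain
    density strictly above ``density_floor``.
    """
    bounds = (ratio_low, ratio_high)
    if not ish_evaluable:
        return LightChainCall(math.nan, "none", "not_evaluable", bounds, density_floor)
    if d_kappa < 0 or d_lambda < 0:
        raise ValueError("light-chain densities must be >= 0")
    if d_lambda == 0:
        ratio = math.inf if d_kappa > 0 else math.nan
    else:
        ratio = d_kappa / d_lambda
    aberrant = (ratio > ratio_high) or (ratio < ratio_low)  # NaN fails both
    substantial = (d_kappa + d_lambda) > density_floor
    if aberrant and substantial:
        side = "kappa" if ratio > ratio_high else "lambda"
        return LightChainCall(ratio, side, "restricted", bounds, density_floor)
    return LightChainCall(ratio, "none", "polytypic", bounds, density_floor)


def aggregate_case(
    case_id: str,
    group: str,
    light_chain_calls: Mapping[str, LightChainCall],
    inflammation_calls: Mapping[str, InflammationCall] | None = None,
) -> CaseSummary:
    """Combine per-biopsy calls into a case-level summary.

    Not-evaluable biopsies are ignored rather than discarding the case: a
    case with one evaluable, restricted biopsy is positive even if the
    other biopsy could not be scored.
    """
    if not light_chain_calls:
        raise ValueError("at least one biopsy call is required")
    calls = list(light_chain_calls.values())
    if all(c.call == "not_evaluable" for c in calls):
        case_lc = "not_evaluable"
    elif any(c.call == "restricted" for c in calls):
        case_lc = "positive"
    else:
        case_lc = "negative"
    inflammation_calls = dict(inflammation_calls or {})
    inflamed = any(c.call == "inflamed" for c in inflammation_calls.values())
    return CaseSummary(
        case_id=case_id,
        group=group,
        biopsy_light_chain=dict(light_chain_calls),
        biopsy_inflammation=inflammation_calls,
        case_light_chain=case_lc,
        case_inflamed=inflamed,
    )


def summarize_light_chain(calls_table: pd.DataFrame) -> dict[str, int]:
    """Cohort-level restriction counts from a per-biopsy call table.

    ``calls_table`` needs columns case_id, site, call, restricted_side with
    call in {restricted, polytypic, not_evaluable}.  Returns the counts a
    clonality survey reports: evaluable/positive cases, evaluable/positive
    specimens, per-chain specimen counts, and the per-site breakdown.
    """
    required = {"case_id", "site", "call", "restricted_side"}
    missing = required - set(calls_table.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")
    t = calls_table
    evaluable = t["call"] != "not_evaluable"
    restricted = t["call"] == "restricted"
    by_case = t.groupby("case_id")["call"]
    case_has_eval = by_case.apply(lambda s: (s != "not_evaluable").any())
    case_positive = by_case.apply(lambda s: (s == "restricted").any())
    hl = t["site"] == "HL"
    bg = t["site"] == "BG"
    return {
        "evaluable_cases": int(case_has_eval.sum()),
        "positive_cases": int((case_positive & case_has_eval).sum()),
        "evaluable_specimens": int(evaluable.sum()),
        "positive_specimens": int(restricted.sum()),
        "kappa_specimens": int((restricted & (t["restricted_side"] == "kappa")).sum()),
        "lambda_specimens": int((restricted & (t["restricted_side"] == "lambda")).sum()),
        "hl_evaluable": int((evaluable & hl).sum()),
        "hl_positive": int((restricted & hl).sum()),
        "bg_evaluable": int((evaluable & bg).sum()),
        "bg_positive": int((restricted & bg).sum()),
    }


def call_specimen_table(
    quant: pd.DataFrame,
    inflammation_cutoff: float = DEFAULT_INFLAMMATION_CUTOFF,
    ratio_low: float = DEFAULT_RATIO_LOW,
    ratio_high: float = DEFAULT_RATIO_HIGH,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
) -> pd.DataFrame:
    """Apply every per-biopsy rule to a specimen quantification table.

    Expects the columns produced by the cohort generator / quantification
    stage (specimen_id, case_id, group, site, d_cd3, d_cd20, d_cd138,
    d_kappa, d_lambda, ish_evaluable).  Adds lymphoplasmacytic_density,
    plasma_cell_ratio, inflammation_call, kl_ratio, call, restricted_side.
    """
    out = quant.copy()
    dens, pratio, icall, klr, lccall, side = [], [], [], [], [], []
    for row in quant.itertuples(index=False):
        d = lymphoplasmacytic_density(row.d_cd3, row.d_cd20, row.d_cd138)
        dens.append(d)
        pratio.append(plasma_cell_ratio(row.d_cd3, row.d_cd20, row.d_cd138))
        icall.append(classify_inflammation(d, inflammation_cutoff).call)
        lc = light_chain_call(
            row.d_kappa, row.d_lambda, bool(row.ish_evaluable),
            ratio_low, ratio_high, density_floor,
        )
        klr.append(lc.kl_ratio)
        lccall.append(lc.call)
        side.append(lc.restricted_side)
    out["lymphoplasmacytic_density"] = dens
    out["plasma_cell_ratio"] = pratio
    out["inflammation_call"] = icall
    out["kl_ratio"] = klr
    out["call"] = lccall
    out["restricted_side"] = side
    return out


def summarize_cases(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-case summary rows from a called specimen table."""
    records = []
    for case_id, sub in calls.groupby("case_id", sort=False):
        lc = {
            r.site: LightChainCall(r.kl_ratio, r.restricted_side, r.call)
            for r in sub.itertuples(index=False)
        }
        infl = {
            r.site: InflammationCall(
                r.lymphoplasmacytic_density, r.inflammation_call
            )
            for r in sub.itertuples(index=False)
        }
        summary = aggregate_case(case_id, sub["group"].iloc[0], lc, infl)
        records.append(
            {
                "case_id": case_id,
                "group": summary.group,
                "case_light_chain": summary.case_light_chain,
                "case_inflamed": summary.case_inflamed,
            }
        )
    return pd.DataFrame(records)
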