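"""Packaged cohort fixtures and the in-study reproduction report.

The ``data/`` CSVs transcribe the published count grids: clinical features
(NHIC vs HIC), eye-graded histology (NHIC / HIC-BG / HIC-HL), the
density-bin x inflammation-grade cross-tabulation, and the per-case
light-chain restriction grid (27 HIC cases x BG/HL biopsy, entries
``+(k)``, ``+(l)``, ``-``, ``NE``).  :func:`reproduce_tables` runs the
package's own summarization and tests over those fixtures and returns
every derived fraction alongside the printed reference values.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from cystiquant.metrics import summarize_light_chain
from cystiquant.stats import (
    ContingencyTable,
    chi2_trend,
    fisher_exact_2x2,
    summarize_inflammation,
)

_SYMBOL_TO_CALL = {
    "+(k)": ("restricted", "kappa"),
    "+(l)": ("restricted", "lambda"),
    "-": ("polytypic", "none"),
    "NE": ("not_evaluable", "none"),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("cystiquant.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Clinical-feature counts, NHIC vs HIC."""
    return _read("table1_clinical.csv")


def load_table2() -> pd.DataFrame:
    """Eye-graded histology counts, NHIC / HIC-BG / HIC-HL."""
    return _read("table2_semiquant.csv")


def load_table2_pvalues() -> pd.DataFrame:
    return _read("table2_pvalues.csv")


def load_table3() -> pd.DataFrame:
    """Density-bin x grade x group cross-tabulation."""
    return _read("table3_inflammation.csv")


def load_table4() -> pd.DataFrame:
    """Raw per-case light-chain grid (columns case, BG, HL)."""
    return _read("table4_light_chain.csv")


def table4_calls() -> pd.DataFrame:
    """The light-chain grid as a per-biopsy call table.

    Columns: case_id, site, call, restricted_side -- the shape
    :func:`cystiquant.metrics.summarize_light_chain` consumes.
    """
    raw = load_table4()
    rows = []
    for rec in raw.itertuples(index=False):
        for site in ("BG", "HL"):
            symbol = str(getattr(rec, site)).strip()
            if symbol not in _SYMBOL_TO_CALL:
                raise ValueError(f"unrecognized grid entry {symbol!r}")
            call, side = _SYMBOL_TO_CALL[symbol]
            rows.append(
                {
                    "case_id": f"HIC-{int(rec.case):03d}",
                    "site": site,
                    "call": call,
                    "restricted_side": side,
                }
            )
    return pd.DataFrame(rows)


def light_chain_summary() -> dict[str, float]:
    """Restriction counts and fractions from the per-case grid."""
    counts = summarize_light_chain(table4_calls())
    out: dict[str, float] = dict(counts)
    out["positive_case_percent"] = round(
        100.0 * counts["positive_cases"] / counts["evaluable_cases"]
    )
    return out


def inflammation_summary() -> dict[str, float]:
    """Inflamed/normal percentages per group from the binned grid."""
    return summarize_inflammation(load_table3())


#: Printed reference values the report compares against.
PRINTED = {
    "HIC_inflamed_percent": 92.6,
    "NHIC_normal_percent": 92.3,
    "NHIC_inflamed_percent_rounded": 8.0,
    "evaluable_cases": 26,
    "positive_cases": 8,
    "positive_case_percent": 31.0,
    "evaluable_specimens": 46,
    "positive_specimens": 9,
    "kappa_specimens": 5,
    "lambda_specimens": 4,
    "hl_positive": 3,
    "hl_evaluable": 21,
    "bg_positive": 6,
    "bg_evaluable": 25,
}


def reproduce_tables() -> pd.DataFrame:
    """Recompute every printed summary fraction from the fixtures.

    Returns a tidy frame with columns quantity, computed, printed, match.
    """
    infl = inflammation_summary()
    lc = light_chain_summary()
    computed = {
        "HIC_inflamed_percent": infl["HIC_inflamed_percent"],
        "NHIC_normal_percent": infl["NHIC_normal_percent"],
        "NHIC_inflamed_percent_rounded": float(
            round(infl["NHIC_inflamed_percent"])
        ),
        **{k: lc[k] for k in (
            "evaluable_cases", "positive_cases", "positive_case_percent",
            "evaluable_specimens", "positive_specimens",
            "kappa_specimens", "lambda_specimens",
            "hl_positive", "hl_evaluable", "bg_positive", "bg_evaluable",
        )},
    }
    rows = []
    for key, printed in PRINTED.items():
        value = float(computed[key])
        rows.append(
            {
                "quantity": key,
                "computed": value,
                "printed": float(printed),
                "match": math.isclose(value, float(printed), abs_tol=1e-9),
            }
        )
    return pd.DataFrame(rows)


def table2_consistency() -> pd.DataFrame:
    """Recompute group-difference p-values for the eye-graded histology grid.

    The original report does not state which test produced each printed
    value, so these are consistency checks: binary features go to Fisher's
    exact test, 3-level ordered features to the trend test.
    """
    grid = load_table2()
    printed = load_table2_pvalues()
    pairs = [("NHIC", "HIC-BG"), ("NHIC", "HIC-HL"), ("HIC-BG", "HIC-HL")]
    rows = []
    for feature, sub in grid.groupby("feature", sort=False):
        for g1, g2 in pairs:
            counts = sub[[g1, g2]].to_numpy().T
            table = ContingencyTable.from_counts(
                counts, row_labels=[g1, g2],
                col_labels=[str(v) for v in sub["level"]],
            )
            if counts.shape[1] == 2:
                res = fisher_exact_2x2(table)
            else:
                res = chi2_trend(table)
            ref = printed[
                (printed["feature"] == feature)
                & (printed["comparison"] == f"{g1} vs {g2}")
            ]["printed_p"]
            rows.append(
                {
                    "feature": feature,
                    "comparison": f"{g1} vs {g2}",
                    "method": res.method,
                    "p_value": res.p_value,
                    "printed_p": ref.iloc[0] if len(ref) else "",
                }
            )
    return pd.DataFrame(rows)
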