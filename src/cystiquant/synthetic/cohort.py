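"""Sample synthetic biopsy cohorts with the study's group structure.

Groups: NHIC (one random bladder biopsy per case), HIC (paired biopsies per
case: background mucosa ``BG`` and Hunner lesion ``HL``), and non-IC
cystitis ``nonIC`` (one biopsy).  Per-marker densities are log-normal per
group; a configurable fraction of HIC cases carries a light-chain-restricted
clone, implemented by multiplying one immunoglobulin light chain by a skew
factor in one (or occasionally both) of the case's biopsies; a configurable
fraction of biopsies is flagged not evaluable for ISH, emulating diffuse
background staining.

Default distribution parameters are calibrated so the binned density
structure (fraction of specimens <200, 200-1000, >1000 cells/mm^2 per
group) and clone prevalence (~30% of HIC cases) resemble the published
cohort; per-specimen raw values are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKERS = ("CD3", "CD20", "CD138", "kappa", "lambda")
GROUPS = ("NHIC", "HIC", "nonIC")

#: Inflammation-grade boundaries on lymphoplasmacytic density (cells/mm^2):
#: grade 0 below the first, grade 2 at or above the second.
DEFAULT_GRADE_BOUNDARIES = (250.0, 1100.0)

#: Epithelium/specimen ratio (%) of a fully epithelialized biopsy, used to
#: convert a sampled ratio into an epithelial-loss fraction.
INTACT_EPITHELIUM_RATIO = 20.0


@dataclass(frozen=True)
class GroupDistributions:
    """Log-normal (meanlog, sdlog) per marker plus a scaled-beta epithelium law."""

    density: dict[str, tuple[float, float]]
    epithelium: tuple[float, float, float]  # (alpha, beta, scale on [0, scale] %)


def _default_distributions() -> dict[str, GroupDistributions]:
    # meanlog in ln(cells/mm^2).  NHIC mucosa is near-normal (total
    # lymphoplasmacytic density mostly <200); HIC and non-IC cystitis are
    # inflamed with medians in the several-hundreds and heavy right tails.
    ln = np.log
    return {
        "NHIC": GroupDistributions(
            density={
                "CD3": (ln(42.0), 0.85),
                "CD20": (ln(16.0), 0.85),
                "CD138": (ln(8.0), 0.85),
                "kappa": (ln(10.0), 0.3),
                "lambda": (ln(5.0), 0.3),
            },
            epithelium=(5.0, 2.0, 25.0),
        ),
        "HIC-BG": GroupDistributions(
            density={
                "CD3": (ln(220.0), 1.45),
                "CD20": (ln(100.0), 1.45),
                "CD138": (ln(80.0), 1.45),
                "kappa": (ln(80.0), 0.3),
                "lambda": (ln(40.0), 0.3),
            },
            epithelium=(2.0, 3.0, 25.0),
        ),
        "HIC-HL": GroupDistributions(
            density={
                "CD3": (ln(240.0), 1.45),
                "CD20": (ln(110.0), 1.45),
                "CD138": (ln(90.0), 1.45),
                "kappa": (ln(90.0), 0.3),
                "lambda": (ln(45.0), 0.3),
            },
            epithelium=(1.2, 5.0, 25.0),
        ),
        "nonIC": GroupDistributions(
            density={
                "CD3": (ln(250.0), 1.2),
                "CD20": (ln(110.0), 1.2),
                "CD138": (ln(60.0), 1.2),
                "kappa": (ln(60.0), 0.3),
                "lambda": (ln(30.0), 0.3),
            },
            epithelium=(5.0, 2.0, 25.0),
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    ``n_cases_per_group`` must contain all of NHIC, HIC, nonIC.  HIC cases
    contribute two biopsy rows (sites BG and HL); the other groups one
    (site NA).  ``clone_probability`` is the per-HIC-case probability of a
    light-chain-restricted clone; ``clone_skew`` multiplies one chain in
    each clone-bearing biopsy.
    """

    n_cases_per_group: dict[str, int] = field(
        default_factory=lambda: {"NHIC": 39, "HIC": 27, "nonIC": 26}
    )
    distributions: dict[str, GroupDistributions] = field(
        default_factory=_default_distributions
    )
    plasma_ratio_shift: float = 0.10
    clone_probability: float = 0.3
    clone_skew: float = 20.0
    ne_probability: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(GROUPS) - set(self.n_cases_per_group)
        if missing:
            raise ValueError(f"n_cases_per_group missing groups: {sorted(missing)}")
        for g, n in self.n_cases_per_group.items():
            if n < 0:
                raise ValueError(f"negative case count for {g}")
        for p in (self.clone_probability, self.ne_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.clone_skew <= 0:
            raise ValueError("clone_skew must be > 0")
        for gname, dist in self.distributions.items():
            for m, (_, sdlog) in dist.density.items():
                if sdlog <= 0:
                    raise ValueError(f"sdlog must be > 0 ({gname}/{m})")


def _sample_biopsy(
    dist: GroupDistributions, rng: np.random.Generator, plasma_shift: float
) -> dict[str, float]:
    row = {
        m: float(rng.lognormal(*dist.density[m])) for m in MARKERS
    }
    if plasma_shift > 0:
        # Additive boost to the CD138 share of lymphoplasmacytic cells,
        # holding CD3 + CD20 fixed.
        total = row["CD3"] + row["CD20"] + row["CD138"]
        share = min(row["CD138"] / total + plasma_shift, 0.9)
        row["CD138"] = share / (1.0 - share) * (row["CD3"] + row["CD20"])
    a, b, scale = dist.epithelium
    row["epithelium_ratio"] = float(rng.beta(a, b)) * scale
    row["epithelium_loss_fraction"] = float(
        np.clip(1.0 - row["epithelium_ratio"] / INTACT_EPITHELIUM_RATIO, 0.0, 1.0)
    )
    return row


def sample_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; deterministic given ``spec.seed``.

    Returns
    -------
    specimen_table
        One row per biopsy: specimen_id, case_id, group, site (BG/HL/NA),
        d_cd3/d_cd20/d_cd138/d_kappa/d_lambda (cells/mm^2),
        epithelium_ratio (%), epithelium_loss_fraction, ish_evaluable,
        clone_planted, clone_side.
    case_table
        One row per case: case_id, group, n_biopsies, clone_planted.

    Draw order is documented and fixed: groups in (NHIC, HIC, nonIC)
    order, cases in index order, and for HIC the BG biopsy before HL, so a
    single root seed reproduces the cohort exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    cases: list[dict] = []
    for group in GROUPS:
        n_cases = spec.n_cases_per_group[group]
        sites = ("BG", "HL") if group == "HIC" else ("NA",)
        for i in range(n_cases):
            case_id = f"{group}-{i + 1:03d}"
            clone_case = group == "HIC" and rng.random() < spec.clone_probability
            if clone_case:
                # Clonal expansion is usually focal: one biopsy involved,
                # occasionally both.
                both = rng.random() < 0.15
                clone_sites = set(sites) if both else {sites[rng.integers(0, 2)]}
                clone_side = "kappa" if rng.random() < 0.6 else "lambda"
            else:
                clone_sites, clone_side = set(), "none"
            for site in sites:
                dist_key = f"HIC-{site}" if group == "HIC" else group
                shift = spec.plasma_ratio_shift if group == "HIC" else 0.0
                row = _sample_biopsy(spec.distributions[dist_key], rng, shift)
                planted = site in clone_sites
                if planted:
                    chain = "kappa" if clone_side == "kappa" else "lambda"
                    row[chain] *= spec.clone_skew
                evaluable = bool(rng.random() >= spec.ne_probability)
                rows.append(
                    {
                        "specimen_id": f"{case_id}-{site}",
                        "case_id": case_id,
                        "group": group,
                        "site": site,
                        "d_cd3": row["CD3"],
                        "d_cd20": row["CD20"],
                        "d_cd138": row["CD138"],
                        "d_kappa": row["kappa"],
                        "d_lambda": row["lambda"],
                        "epithelium_ratio": row["epithelium_ratio"],
                        "epithelium_loss_fraction": row["epithelium_loss_fraction"],
                        "ish_evaluable": evaluable,
                        "clone_planted": planted,
                        "clone_side": clone_side if planted else "none",
                    }
                )
            cases.append(
                {
                    "case_id": case_id,
                    "group": group,
                    "n_biopsies": len(sites),
                    "clone_planted": clone_case,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(cases)


def assign_semiquant_grades(
    specimen_table: pd.DataFrame,
    grade_boundaries: tuple[float, float] = DEFAULT_GRADE_BOUNDARIES,
) -> pd.DataFrame:
    """Add eye-style semi-quantitative grades to a specimen table.

    ``inflammation_grade`` (0/1/2) is mapped from the total
    lymphoplasmacytic density with the given boundaries (upper grade on
    ties).  ``epithelial_loss_grade`` follows the conventional thirds rule:
    grade 0 below 1/3 lost, grade 1 from 1/3 to 2/3, grade 2 above 2/3,
    with exact thirds assigned to the higher grade.
    """
    lo, hi = grade_boundaries
    if not 0 <= lo < hi:
        raise ValueError("grade boundaries must satisfy 0 <= low < high")
    loss = specimen_table["epithelium_loss_fraction"].to_numpy(dtype=float)
    if np.any((loss < 0) | (loss > 1)):
        raise ValueError("epithelium_loss_fraction must lie in [0, 1]")
    out = specimen_table.copy()
    density = (
        out["d_cd3"].to_numpy() + out["d_cd20"].to_numpy() + out["d_cd138"].to_numpy()
    )
    out["inflammation_grade"] = np.select(
        [density < lo, density < hi], [0, 1], default=2
    )
    out["epithelial_loss_grade"] = np.select(
        [loss < 1.0 / 3.0, loss < 2.0 / 3.0], [0, 1], default=2
    )
    return out
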