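"""Era-composition statistics over called binding sites.

The counting unit throughout is the *site residue*: each residue of a
consensus binding site counts once per site, regardless of how many
structures or atomic contacts support it.  Percentages are reported per
coenzyme temporality (or per coenzyme class), against a background given
by the full sequence set.

Statistical machinery:

* Pearson chi-squared, either as an r x k contingency test or as a
  goodness-of-fit test against stated expected counts; no continuity
  correction; p-values from the chi-squared survival function and reported
  raw (no multiple-testing correction).
* Fractional difference (FD): for each amino acid, the difference in its
  relative binding-site frequency (in percentage points) between two
  temporalities, plus the mean FD over the early and the late residue sets.
* A background (enrichment-ratio) normalization of early/late proportions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binding_sites import BindingSite
from .registry import Era, Registry, Temporality

logger = logging.getLogger(__name__)

TEMPORALITY_ORDER = [
    Temporality.ANCIENT, Temporality.LUCA, Temporality.POST_LUCA,
    Temporality.UNCLASSIFIED,
]


def _era_counts(residue_names: Iterable[str], registry: Registry) -> Counter:
    counts = Counter()
    for name in residue_names:
        counts[registry.lookup_era(name)] += 1
    return counts


def site_composition(
    sites: Sequence[BindingSite],
    registry: Registry,
    group_by: str = "temporality",
) -> pd.DataFrame:
    """Early/late composition of site residues, per temporality or class.

    Returns a DataFrame indexed by group with columns ``early_count``,
    ``late_count``, ``early_pct``, ``late_pct``.  Empty groups are omitted.
    """
    if group_by not in ("temporality", "coenzyme_class"):
        raise ValueError("group_by must be 'temporality' or 'coenzyme_class'")
    rows = {}
    for site in sites:
        key = (
            site.temporality.value if group_by == "temporality"
            else site.coenzyme_class
        )
        c = rows.setdefault(key, Counter())
        c.update(_era_counts((r.residue_name for r in site.residues), registry))
    if group_by == "temporality":
        order = [t.value for t in TEMPORALITY_ORDER if t.value in rows]
    else:
        order = sorted(rows)
    data = []
    for key in order:
        c = rows[key]
        total = c[Era.EARLY] + c[Era.LATE]
        if total == 0:
            logger.warning("group %s has no site residues; omitted", key)
            continue
        data.append({
            "group": key,
            "early_count": c[Era.EARLY],
            "late_count": c[Era.LATE],
            "early_pct": 100.0 * c[Era.EARLY] / total,
            "late_pct": 100.0 * c[Era.LATE] / total,
        })
    return pd.DataFrame(data).set_index("group") if data else pd.DataFrame(
        columns=["early_count", "late_count", "early_pct", "late_pct"]
    )


def background_composition(
    sequences: Mapping[str, str], registry: Registry
) -> dict:
    """Early/late percentages over all residues of all sequences.

    Non-canonical letters (X, B, Z, ...) are excluded and counted.
    """
    if not sequences:
        raise ValueError("at least one sequence is required")
    counts = Counter()
    n_noncanonical = 0
    for seq in sequences.values():
        for ch in seq:
            if registry.is_standard_residue(ch):
                counts[registry.lookup_era(ch)] += 1
            else:
                n_noncanonical += 1
    total = counts[Era.EARLY] + counts[Era.LATE]
    if total == 0:
        raise ValueError("sequences contain no canonical residues")
    if n_noncanonical:
        logger.info("excluded %d non-canonical residues", n_noncanonical)
    return {
        "early_count": counts[Era.EARLY],
        "late_count": counts[Era.LATE],
        "early_pct": 100.0 * counts[Era.EARLY] / total,
        "late_pct": 100.0 * counts[Era.LATE] / total,
        "n_noncanonical_excluded": n_noncanonical,
    }


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    low_expected_warning: bool

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "low_expected_warning": self.low_expected_warning,
        }


def chi_squared(
    observed, expected=None
) -> ChiSquaredResult:
    """Pearson chi-squared test.

    With ``expected=None`` the input is an r x k contingency table and the
    expected counts come from its margins (df = (r-1)(k-1)).  With explicit
    ``expected`` the test is goodness-of-fit over k cells (df = k-1).
    No continuity correction.  A zero expected count is an error; any
    expected count below 5 sets a warning flag on the result.
    """
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        if obs.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        total = obs.sum()
        if total <= 0:
            raise ValueError("table total must be positive")
        exp = row @ col / total
        df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    else:
        exp = np.asarray(expected, dtype=float)
        obs = obs.ravel()
        exp = exp.ravel()
        if obs.shape != exp.shape:
            raise ValueError("observed and expected must have the same shape")
        df = obs.size - 1
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return ChiSquaredResult(
        statistic=stat,
        df=df,
        p_value=p,
        low_expected_warning=bool(np.any(exp < 5)),
    )


def site_aa_composition(
    sites: Sequence[BindingSite],
    registry: Registry,
    temporality: Temporality | str,
) -> dict[str, float]:
    """Per-amino-acid relative frequency (%) among one temporality's sites.

    All 20 residues appear in the output, zero-frequency ones included.
    """
    temporality = Temporality(temporality)
    counts = Counter()
    for site in sites:
        if site.temporality is temporality:
            counts.update(r.residue_name for r in site.residues)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no site residues for temporality {temporality}")
    return {
        aa: 100.0 * counts.get(aa, 0) / total
        for aa in sorted(registry.amino_acids)
    }


def fractional_difference(
    comp_a: Mapping[str, float],
    comp_b: Mapping[str, float],
    registry: Registry,
) -> pd.DataFrame:
    """Per-amino-acid FD between two compositions, in percentage points.

    FD_i = freq_i(A) - freq_i(B).  The frame carries ``mean_fd_early`` and
    ``mean_fd_late`` in ``attrs``.  Antisymmetric by construction.
    """
    aas = sorted(registry.amino_acids)
    for comp, label in ((comp_a, "A"), (comp_b, "B")):
        missing = set(aas) - set(comp)
        if missing:
            raise ValueError(
                f"composition {label} missing residues: {sorted(missing)}"
            )
        s = sum(comp[aa] for aa in aas)
        if abs(s - 100.0) > 1e-6:
            raise ValueError(f"composition {label} sums to {s}, not 100")
    df = pd.DataFrame({
        "freq_a": [comp_a[aa] for aa in aas],
        "freq_b": [comp_b[aa] for aa in aas],
    }, index=pd.Index(aas, name="residue"))
    df["fd"] = df["freq_a"] - df["freq_b"]
    df["era"] = [registry.lookup_era(aa).value for aa in aas]
    df.attrs["mean_fd_early"] = float(df.loc[df["era"] == "early", "fd"].mean())
    df.attrs["mean_fd_late"] = float(df.loc[df["era"] == "late", "fd"].mean())
    return df


def phosphate_sensitivity(
    sites: Sequence[BindingSite],
    registry: Registry,
    group_by: str = "temporality",
) -> pd.DataFrame:
    """Era composition restricted to phosphate-free coenzyme classes.

    Sensitivity analysis for the possibility that the early/late trend is
    driven purely by phosphate-group binding.
    """
    kept = [
        s for s in sites
        if not registry.coenzyme_class(s.coenzyme_class).phosphate_containing
    ]
    if not kept:
        logger.warning("no sites remain after excluding phosphate-containing "
                       "coenzyme classes")
    return site_composition(kept, registry, group_by=group_by)


def normalize_by_background(
    early_pct: float, late_pct: float,
    background_early_pct: float, background_late_pct: float,
) -> tuple[float, float]:
    """Enrichment-ratio normalization of an early/late split.

    Each era share is divided by its background share, and the two
    enrichment ratios are rescaled to sum to 100.  A composition equal to
    the background therefore maps to 50/50, and a 50/50 background leaves
    the composition unchanged.
    """
    if background_early_pct <= 0 or background_late_pct <= 0:
        raise ValueError("background percentages must be positive")
    e = early_pct / background_early_pct
    l = late_pct / background_late_pct
    total = e + l
    if total == 0:
        raise ValueError("composition is empty")
    return 100.0 * e / total, 100.0 * l / total
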