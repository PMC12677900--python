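"""Binding-mode analytics over called sites.

Three views of how coenzymes are held by their sites:

* contact-mode partition — what fraction of site residues touch the ligand
  through backbone atoms only, side-chain atoms only, or both, per
  coenzyme temporality, with an early/late era split inside each mode;
* grouped interaction-type distribution — how contributions spread over
  the eight non-clash grouped types (a residue contributes once to every
  group it exhibits; an alternative "dominant" counting mode assigns each
  residue a single group by a fixed precedence);
* metal mediation — the fraction of sites with at least one metal ion in
  the coenzyme's binding environment, per temporality, and per-class
  per-element breakdowns.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Sequence

import pandas as pd

from .binding_sites import BindingSite, ContactMode
from .composition_stats import TEMPORALITY_ORDER, chi_squared
from .registry import ContactGroup, Era, Registry

logger = logging.getLogger(__name__)

MODE_ORDER = [
    ContactMode.BACKBONE_ONLY, ContactMode.SIDECHAIN_ONLY, ContactMode.BOTH,
]

#: Grouped types reported in distributions (clashes are always excluded).
REPORTED_GROUPS = [
    ContactGroup.COVALENT, ContactGroup.ELECTROSTATIC, ContactGroup.AMIDE,
    ContactGroup.VDW, ContactGroup.HYDROPHOBIC, ContactGroup.AROMATIC,
    ContactGroup.ATOM_PI, ContactGroup.METAL,
]

#: Precedence used by the "dominant" counting mode: specific chemistry
#: before generic proximity.
DOMINANT_PRECEDENCE = [
    ContactGroup.COVALENT, ContactGroup.METAL, ContactGroup.ELECTROSTATIC,
    ContactGroup.AROMATIC, ContactGroup.ATOM_PI, ContactGroup.AMIDE,
    ContactGroup.HYDROPHOBIC, ContactGroup.VDW,
]


def mode_distribution(
    sites: Sequence[BindingSite], registry: Registry
) -> pd.DataFrame:
    """Contact-mode percentages per temporality, with era split and chi2.

    One row per (temporality, mode); columns carry the residue count, the
    percentage within the temporality, and the early/late counts inside the
    mode.  A per-temporality era x mode chi-squared result is stored in
    ``attrs["chi_squared"]``.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    era_counts: dict[tuple[str, ContactMode], Counter] = defaultdict(Counter)
    for site in sites:
        t = site.temporality.value
        for res in site.residues:
            counts[t][res.contact_mode] += 1
            era_counts[(t, res.contact_mode)][res.era] += 1
    rows = []
    chis = {}
    for temp in [t.value for t in TEMPORALITY_ORDER if t.value in counts]:
        total = sum(counts[temp].values())
        for mode in MODE_ORDER:
            n = counts[temp][mode]
            ec = era_counts[(temp, mode)]
            rows.append({
                "temporality": temp,
                "mode": mode.value,
                "n_residues": n,
                "pct": 100.0 * n / total,
                "early_count": ec[Era.EARLY],
                "late_count": ec[Era.LATE],
            })
        # era x mode contingency for this temporality (non-empty modes only)
        table = [
            [era_counts[(temp, m)][Era.EARLY], era_counts[(temp, m)][Era.LATE]]
            for m in MODE_ORDER
            if sum(era_counts[(temp, m)].values()) > 0
        ]
        if len(table) >= 2 and all(sum(col) > 0 for col in zip(*table)):
            chis[temp] = chi_squared(table)
    df = pd.DataFrame(rows)
    df.attrs["chi_squared"] = chis
    return df


def type_distribution(
    sites: Sequence[BindingSite],
    registry: Registry,
    counting: str = "per_type",
) -> pd.DataFrame:
    """Grouped interaction-type percentages per temporality.

    ``counting="per_type"`` (default): a residue contributes once to every
    grouped type it exhibits, so percentages are over (residue, type)
    contributions.  ``counting="dominant"``: each residue contributes to a
    single group chosen by a fixed precedence order.  Clash-only residues
    never reach this stage.
    """
    if counting not in ("per_type", "dominant"):
        raise ValueError("counting must be 'per_type' or 'dominant'")
    counts: dict[str, Counter] = defaultdict(Counter)
    for site in sites:
        t = site.temporality.value
        for res in site.residues:
            groups = res.grouped_types - {ContactGroup.CLASHES}
            if not groups:
                continue
            if counting == "dominant":
                dom = next(g for g in DOMINANT_PRECEDENCE if g in groups)
                counts[t][dom] += 1
            else:
                for g in groups:
                    counts[t][g] += 1
    rows = []
    for temp in [t.value for t in TEMPORALITY_ORDER if t.value in counts]:
        total = sum(counts[temp].values())
        for g in REPORTED_GROUPS:
            rows.append({
                "temporality": temp,
                "grouped_type": g.value,
                "n_contributions": counts[temp][g],
                "pct": 100.0 * counts[temp][g] / total,
            })
    return pd.DataFrame(rows)


def metal_mediation(
    sites: Sequence[BindingSite], registry: Registry
) -> dict:
    """Metal-ion mediation profile.

    Returns a dict with:

    * ``by_temporality`` — DataFrame: fraction of sites with >= 1 metal ion;
    * ``by_class_element`` — DataFrame: per coenzyme class, per element,
      the fraction of that class's sites involving the element (set
      semantics: a site counts once per element regardless of copy number);
    * ``element_ranking`` — elements ordered by the number of sites they
      mediate (ties broken alphabetically).
    """
    temp_total: Counter = Counter()
    temp_metal: Counter = Counter()
    class_total: Counter = Counter()
    class_element: dict[str, Counter] = defaultdict(Counter)
    element_sites: Counter = Counter()
    for site in sites:
        t = site.temporality.value
        temp_total[t] += 1
        class_total[site.coenzyme_class] += 1
        if site.has_metal:
            temp_metal[t] += 1
        for element in site.metal_elements:
            class_element[site.coenzyme_class][element] += 1
            element_sites[element] += 1
    by_temp = pd.DataFrame([
        {
            "temporality": t.value,
            "n_sites": temp_total[t.value],
            "n_with_metal": temp_metal[t.value],
            "fraction_with_metal": temp_metal[t.value] / temp_total[t.value],
        }
        for t in TEMPORALITY_ORDER if temp_total[t.value] > 0
    ])
    rows = []
    for cls in sorted(class_element):
        for element in sorted(class_element[cls]):
            rows.append({
                "coenzyme_class": cls,
                "element": element,
                "n_sites": class_element[cls][element],
                "fraction": class_element[cls][element] / class_total[cls],
            })
    by_class = pd.DataFrame(
        rows, columns=["coenzyme_class", "element", "n_sites", "fraction"]
    )
    ranking = sorted(element_sites, key=lambda e: (-element_sites[e], e))
    return {
        "by_temporality": by_temp,
        "by_class_element": by_class,
        "element_ranking": ranking,
    }
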