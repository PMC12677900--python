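"""Consensus binding-site calling at the UniProt level.

A protein (one UniProt accession) is usually represented by several
structures.  For each (protein, coenzyme class) pair, the *interaction
ratio* of a residue is the fraction of that protein's structures in which
the residue contacts the coenzyme.  Residues whose ratio reaches the
calling threshold (default: at least 50%) form the consensus binding site.
Ratios are kept as exact rationals so that ties at the threshold behave
predictably; whether a ratio exactly equal to the threshold qualifies is a
config flag (inclusive by default).

Each site residue also carries its contact mode — backbone-only (atoms
N, C, CA, O), side-chain-only, or both — aggregated over all structures,
the set of grouped interaction types it exhibits, and its amino-acid era.
Metal ions observed in the same bound-molecule environment as the coenzyme
mark the site as metal-mediated.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

from .ingest import LiftedContact
from .manifest import Manifest
from .registry import (
    BACKBONE_ATOMS,
    ContactGroup,
    Era,
    Registry,
    Temporality,
    classify_contact_group,
    is_clash_only,
)

logger = logging.getLogger(__name__)


class ContactMode(str, Enum):
    BACKBONE_ONLY = "backbone_only"
    SIDECHAIN_ONLY = "sidechain_only"
    BOTH = "both"


def compute_interaction_ratio(presence: Sequence[bool]) -> Fraction:
    """Exact fraction of structures in which the residue interacts."""
    if len(presence) == 0:
        raise ValueError("presence vector must cover at least one structure")
    return Fraction(sum(bool(x) for x in presence), len(presence))


def classify_contact_mode(atom_names: Iterable[str]) -> ContactMode:
    """Backbone-only / side-chain-only / both from the contacting atoms."""
    atoms = {a.upper() for a in atom_names}
    if not atoms:
        raise ValueError("atom_names must be non-empty")
    if atoms <= BACKBONE_ATOMS:
        return ContactMode.BACKBONE_ONLY
    if atoms.isdisjoint(BACKBONE_ATOMS):
        return ContactMode.SIDECHAIN_ONLY
    return ContactMode.BOTH


@dataclass(frozen=True)
class SiteResidue:
    uniprot_position: int
    residue_name: str
    interaction_ratio: Fraction
    contact_mode: ContactMode
    grouped_types: frozenset[ContactGroup]
    era: Era
    atom_names: frozenset[str]


@dataclass
class BindingSite:
    uniprot_accession: str
    coenzyme_class: str
    temporality: Temporality
    residues: list[SiteResidue]
    n_structures: int
    metal_ions: Counter = field(default_factory=Counter)
    secondary_structure_profile: dict[int, frozenset[str]] = field(
        default_factory=dict
    )

    @property
    def positions(self) -> list[int]:
        return [r.uniprot_position for r in self.residues]

    @property
    def metal_elements(self) -> frozenset[str]:
        return frozenset(self.metal_ions)

    @property
    def has_metal(self) -> bool:
        return bool(self.metal_ions)


def _threshold_fraction(threshold: float | Fraction) -> Fraction:
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(threshold).limit_denominator(10**6)


def call_sites(
    contacts: Sequence[LiftedContact],
    registry: Registry,
    threshold: float | Fraction = Fraction(1, 2),
    inclusive: bool = True,
    manifest: Manifest | None = None,
    on_unknown_label: str = "warn",
) -> list[BindingSite]:
    """Call consensus binding sites from UniProt-lifted contacts.

    One site is produced per (accession, coenzyme class) pair that has at
    least one residue whose interaction ratio qualifies.  ``n_structures``
    counts the distinct structures of the accession in which the class is
    bound.  Sites and their residues are deterministically ordered.
    """
    manifest = manifest or Manifest()
    sec = manifest.section("contacts")
    th = _threshold_fraction(threshold)

    coenzyme_recs: list[tuple[LiftedContact, frozenset[ContactGroup], str]] = []
    metal_recs: list[LiftedContact] = []
    # (structure, environment) -> class names bound in that environment
    env_classes: dict[tuple[str, str], set[str]] = defaultdict(set)

    for rec in contacts:
        if rec.partner_is_metal:
            metal_recs.append(rec)
            continue
        groups = classify_contact_group(rec.raw_labels, on_unknown_label)
        if not groups or is_clash_only(groups):
            sec.drop("clash_only")
            continue
        cls = registry.class_for_ligand(rec.ligand_code)
        if cls is None:
            sec.drop("unregistered_ligand")
            continue
        if cls.excluded:
            sec.drop("excluded_class")
            continue
        coenzyme_recs.append((rec, groups, cls.class_name))
        env_classes[(rec.structure_id, rec.environment)].add(cls.class_name)

    # group by (accession, class)
    by_site: dict[tuple[str, str], list[tuple[LiftedContact, frozenset]]] = (
        defaultdict(list)
    )
    for rec, groups, cls_name in coenzyme_recs:
        by_site[(rec.uniprot_accession, cls_name)].append((rec, groups))

    sites: list[BindingSite] = []
    for (acc, cls_name), recs in sorted(by_site.items()):
        structures = sorted({r.structure_id for r, _ in recs})
        n_structures = len(structures)
        by_pos: dict[int, list[tuple[LiftedContact, frozenset]]] = defaultdict(
            list
        )
        for r, g in recs:
            by_pos[r.uniprot_position].append((r, g))
        residues: list[SiteResidue] = []
        for pos in sorted(by_pos):
            pos_recs = by_pos[pos]
            present_in = {r.structure_id for r, _ in pos_recs}
            ratio = Fraction(len(present_in), n_structures)
            qualifies = ratio >= th if inclusive else ratio > th
            if not qualifies:
                sec.drop("below_threshold", len(pos_recs))
                continue
            sec.use("used_site", len(pos_recs))
            name_counts = Counter(r.residue_name for r, _ in pos_recs)
            resname = min(
                name_counts, key=lambda n: (-name_counts[n], n)
            )
            atoms = frozenset(r.atom_name for r, _ in pos_recs)
            grouped = frozenset().union(*(g for _, g in pos_recs)) - {
                ContactGroup.CLASHES
            }
            residues.append(SiteResidue(
                uniprot_position=pos,
                residue_name=resname,
                interaction_ratio=ratio,
                contact_mode=classify_contact_mode(atoms),
                grouped_types=grouped,
                era=registry.lookup_era(resname),
                atom_names=atoms,
            ))
        if residues:
            sites.append(BindingSite(
                uniprot_accession=acc,
                coenzyme_class=cls_name,
                temporality=registry.lookup_temporality(cls_name),
                residues=residues,
                n_structures=n_structures,
            ))
    if not sites:
        logger.warning("no binding site qualified at threshold %s", th)

    # attach metal ions via the shared bound-molecule environment
    site_index = {
        (s.uniprot_accession, s.coenzyme_class): s for s in sites
    }
    for rec in metal_recs:
        classes = env_classes.get((rec.structure_id, rec.environment), ())
        attached = False
        for cls_name in classes:
            site = site_index.get((rec.uniprot_accession, cls_name))
            if site is not None:
                # one ion copy per (structure, ion instance, element)
                site.metal_ions[
                    (rec.structure_id, rec.ligand_instance, rec.ligand_code)
                ] = 1
                attached = True
        if attached:
            sec.use("used_metal")
        else:
            sec.drop("metal_unassociated")
    for site in sites:
        site.metal_ions = Counter(
            element for (_, _, element) in site.metal_ions
        )
    return sites
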