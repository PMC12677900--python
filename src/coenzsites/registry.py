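"""Evolutionary classification registry for amino acids and coenzyme classes.

The registry holds two fixed tables that drive every downstream statistic:

* the 20 canonical amino acids, split into an *early* era (the ~10 residues
  considered prebiotically plausible: Ala, Asp, Glu, Gly, Ile, Leu, Pro,
  Ser, Thr, Val) and a *late* era (the residues attributed to later
  biosynthesis), each with a chronology rank used only for report ordering;
* the coenzyme classes, each labelled with an evolutionary *temporality*
  (Ancient / LUCA / Post-LUCA / Unclassified), a nucleotide-derived flag,
  a phosphate-containing flag, and the set of chemical-component (ligand)
  codes that realise the class in structure files.

The registry is loaded from a single declarative YAML file; a canonical
copy ships with the package (``data/registry.yaml``).  The module also owns
the mapping from raw atomic-contact labels (Arpeggio-style vocabulary) onto
the nine grouped interaction types used throughout the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Era",
    "Temporality",
    "ContactGroup",
    "AminoAcidRecord",
    "CoenzymeClassRecord",
    "Registry",
    "load_registry",
    "dump_registry",
    "contact_group",
    "classify_contact_group",
    "is_clash_only",
    "BACKBONE_ATOMS",
    "SIDECHAIN_ATOMS",
    "METAL_ELEMENTS",
    "RAW_LABEL_GROUPS",
]


class Era(str, Enum):
    EARLY = "early"
    LATE = "late"


class Temporality(str, Enum):
    ANCIENT = "Ancient"
    LUCA = "LUCA"
    POST_LUCA = "Post-LUCA"
    UNCLASSIFIED = "Unclassified"


class ContactGroup(str, Enum):
    """The nine grouped interaction types."""

    COVALENT = "covalent"
    ELECTROSTATIC = "electrostatic"
    AMIDE = "amide"
    VDW = "vdw"
    HYDROPHOBIC = "hydrophobic"
    AROMATIC = "aromatic"
    ATOM_PI = "atom-pi"
    METAL = "metal"
    CLASHES = "clashes"


#: Backbone heavy atoms of every standard amino acid.
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "C", "CA", "O"})

#: Side-chain heavy atoms per residue (PDB atom-name conventions).
#: Glycine has no side-chain heavy atom.
SIDECHAIN_ATOMS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"}),
    "ASN": frozenset({"CB", "CG", "OD1", "ND2"}),
    "ASP": frozenset({"CB", "CG", "OD1", "OD2"}),
    "CYS": frozenset({"CB", "SG"}),
    "GLN": frozenset({"CB", "CG", "CD", "OE1", "NE2"}),
    "GLU": frozenset({"CB", "CG", "CD", "OE1", "OE2"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB", "CG", "ND1", "CD2", "CE1", "NE2"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD", "CE", "NZ"}),
    "MET": frozenset({"CB", "CG", "SD", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG", "CD"}),
    "SER": frozenset({"CB", "OG"}),
    "THR": frozenset({"CB", "OG1", "CG2"}),
    "TRP": frozenset({"CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                      "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

#: Chemical-component codes treated as free metal ions when they appear as
#: the contact partner.  Covers the biologically common mono/divalent ions.
METAL_ELEMENTS: frozenset[str] = frozenset({
    "MG", "CA", "MN", "FE", "FE2", "ZN", "NA", "K", "CU", "CU1", "NI",
    "CO", "MO", "W", "CD", "HG", "SR", "BA", "LI", "CS", "RB", "AL",
    "3CO", "MN3",
})

#: Raw contact-label vocabulary -> grouped interaction type.
#: Lower-case labels are atom-atom contact types; upper-case labels are
#: ring-ring / atom-ring geometries.
RAW_LABEL_GROUPS: dict[str, ContactGroup] = {
    "covalent": ContactGroup.COVALENT,
    # electrostatic family
    "ionic": ContactGroup.ELECTROSTATIC,
    "hbond": ContactGroup.ELECTROSTATIC,
    "weak_hbond": ContactGroup.ELECTROSTATIC,
    "polar": ContactGroup.ELECTROSTATIC,
    "weak_polar": ContactGroup.ELECTROSTATIC,
    "xbond": ContactGroup.ELECTROSTATIC,
    "carbonyl": ContactGroup.ELECTROSTATIC,
    # amide stacking
    "AMIDEAMIDE": ContactGroup.AMIDE,
    "AMIDERING": ContactGroup.AMIDE,
    # simple contacts
    "vdw": ContactGroup.VDW,
    "hydrophobic": ContactGroup.HYDROPHOBIC,
    # aromatic ring-ring geometries
    "aromatic": ContactGroup.AROMATIC,
    "FF": ContactGroup.AROMATIC,
    "OF": ContactGroup.AROMATIC,
    "EE": ContactGroup.AROMATIC,
    "FT": ContactGroup.AROMATIC,
    "OT": ContactGroup.AROMATIC,
    "ET": ContactGroup.AROMATIC,
    "FE": ContactGroup.AROMATIC,
    "OE": ContactGroup.AROMATIC,
    "EF": ContactGroup.AROMATIC,
    # atom-ring (pi) interactions
    "CARBONPI": ContactGroup.ATOM_PI,
    "CATIONPI": ContactGroup.ATOM_PI,
    "DONORPI": ContactGroup.ATOM_PI,
    "HALOGENPI": ContactGroup.ATOM_PI,
    "METSULPHURPI": ContactGroup.ATOM_PI,
    # metal coordination
    "metal": ContactGroup.METAL,
    # steric clashes, omitted from all downstream statistics
    "clash": ContactGroup.CLASHES,
    "vdw_clash": ContactGroup.CLASHES,
}


def contact_group(label: str) -> ContactGroup:
    """Map one raw contact label onto its grouped interaction type.

    Raises ``KeyError`` for labels outside the known vocabulary.
    """
    return RAW_LABEL_GROUPS[label]


def classify_contact_group(
    raw_labels: Iterable[str], on_unknown: str = "warn"
) -> frozenset[ContactGroup]:
    """Group a contact record's raw labels into interaction types.

    Parameters
    ----------
    raw_labels
        Raw contact-type strings attached to one residue-ligand contact.
    on_unknown
        ``"warn"`` (default) logs and skips labels outside the vocabulary;
        ``"reject"`` raises ``ValueError``.

    Returns
    -------
    frozenset of :class:`ContactGroup` — every group represented among the
    labels.  A record whose only group is ``clashes`` should be dropped
    downstream (see :func:`is_clash_only`).
    """
    groups: set[ContactGroup] = set()
    for label in raw_labels:
        try:
            groups.add(RAW_LABEL_GROUPS[label])
        except KeyError:
            if on_unknown == "reject":
                raise ValueError(f"unknown contact label: {label!r}") from None
            logger.warning("skipping unknown contact label %r", label)
    return frozenset(groups)


def is_clash_only(groups: frozenset[ContactGroup]) -> bool:
    """True when a record's labels reduce to steric clashes alone."""
    return bool(groups) and groups <= {ContactGroup.CLASHES}


@dataclass(frozen=True)
class AminoAcidRecord:
    three_letter_code: str
    one_letter_code: str
    era: Era
    chronology_rank: int
    backbone_atom_names: frozenset[str] = BACKBONE_ATOMS


@dataclass(frozen=True)
class CoenzymeClassRecord:
    class_name: str
    temporality: Temporality
    nucleotide_derived: bool
    phosphate_containing: bool
    member_ligand_codes: frozenset[str]
    excluded: bool = False


@dataclass(frozen=True)
class Registry:
    """Immutable lookup object over the amino-acid and coenzyme tables."""

    amino_acids: Mapping[str, AminoAcidRecord]
    coenzyme_classes: Mapping[str, CoenzymeClassRecord]
    _one_letter_index: Mapping[str, str] = field(default_factory=dict)
    _ligand_index: Mapping[str, str] = field(default_factory=dict)

    # -- amino-acid lookups -------------------------------------------------
    def amino_acid(self, code: str) -> AminoAcidRecord:
        code = code.upper()
        if len(code) == 1:
            code = self._one_letter_index[code]
        return self.amino_acids[code]

    def lookup_era(self, code: str) -> Era:
        return self.amino_acid(code).era

    def is_standard_residue(self, code: str) -> bool:
        code = code.upper()
        return code in self.amino_acids or code in self._one_letter_index

    @property
    def early_residues(self) -> frozenset[str]:
        return frozenset(
            c for c, r in self.amino_acids.items() if r.era is Era.EARLY
        )

    @property
    def late_residues(self) -> frozenset[str]:
        return frozenset(
            c for c, r in self.amino_acids.items() if r.era is Era.LATE
        )

    # -- coenzyme lookups ---------------------------------------------------
    def coenzyme_class(self, name: str) -> CoenzymeClassRecord:
        return self.coenzyme_classes[name]

    def lookup_temporality(self, class_name: str) -> Temporality:
        return self.coenzyme_classes[class_name].temporality

    def class_for_ligand(self, ligand_code: str) -> CoenzymeClassRecord | None:
        name = self._ligand_index.get(ligand_code.upper())
        return self.coenzyme_classes[name] if name else None

    @property
    def analyzed_classes(self) -> list[CoenzymeClassRecord]:
        return [c for c in self.coenzyme_classes.values() if not c.excluded]

    def classes_of(self, temporality: Temporality) -> list[CoenzymeClassRecord]:
        return [
            c for c in self.analyzed_classes if c.temporality is temporality
        ]

    def is_metal(self, ligand_code: str) -> bool:
        return ligand_code.upper() in METAL_ELEMENTS

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        aas = self.amino_acids
        if len(aas) != 20:
            raise ValueError(f"expected 20 amino acids, got {len(aas)}")
        early = {c for c, r in aas.items() if r.era is Era.EARLY}
        expected_early = {
            "ALA", "ASP", "GLU", "GLY", "ILE", "LEU", "PRO", "SER", "THR",
            "VAL",
        }
        if early != expected_early:
            raise ValueError(f"early-era residue set is wrong: {sorted(early)}")
        ranks = sorted(r.chronology_rank for r in aas.values())
        if ranks != list(range(1, 21)):
            raise ValueError("chronology ranks must be a permutation of 1..20")
        for rec in aas.values():
            if rec.backbone_atom_names != BACKBONE_ATOMS:
                raise ValueError(
                    f"{rec.three_letter_code}: backbone atoms must be N,C,CA,O"
                )
        classes = self.coenzyme_classes
        if len(classes) != 28:
            raise ValueError(f"expected 28 coenzyme classes, got {len(classes)}")
        unclassified = {
            c.class_name
            for c in classes.values()
            if c.temporality is Temporality.UNCLASSIFIED
        }
        expected_unclassified = {
            "Thiamine diphosphate", "Coenzyme M", "Factor F430", "Glutathione",
        }
        if unclassified != expected_unclassified:
            raise ValueError(
                f"Unclassified set is wrong: {sorted(unclassified)}"
            )
        for c in classes.values():
            if c.nucleotide_derived and c.temporality is not Temporality.ANCIENT:
                raise ValueError(
                    f"{c.class_name}: nucleotide-derived implies Ancient"
                )
        seen: dict[str, str] = {}
        for c in classes.values():
            for lig in c.member_ligand_codes:
                if lig in seen:
                    raise ValueError(
                        f"ligand code {lig} in both {seen[lig]} and "
                        f"{c.class_name}"
                    )
                seen[lig] = c.class_name


def _parse_registry(doc: dict) -> Registry:
    if doc.get("schema") != 1:
        raise ValueError("registry config must declare 'schema: 1'")
    aas: dict[str, AminoAcidRecord] = {}
    one_letter: dict[str, str] = {}
    for row in doc["amino_acids"]:
        try:
            era = Era(row["era"])
        except ValueError:
            raise ValueError(f"unknown era value: {row['era']!r}") from None
        rec = AminoAcidRecord(
            three_letter_code=row["three"].upper(),
            one_letter_code=row["one"].upper(),
            era=era,
            chronology_rank=int(row["rank"]),
        )
        aas[rec.three_letter_code] = rec
        one_letter[rec.one_letter_code] = rec.three_letter_code
    classes: dict[str, CoenzymeClassRecord] = {}
    ligand_index: dict[str, str] = {}
    for row in doc["coenzyme_classes"]:
        try:
            temp = Temporality(row["temporality"])
        except ValueError:
            raise ValueError(
                f"unknown temporality value: {row['temporality']!r}"
            ) from None
        ligs = frozenset(str(x).upper() for x in row.get("ligands", []))
        for lig in ligs:
            if len(lig) > 5 or not lig.isalnum():
                raise ValueError(f"bad ligand code {lig!r} in {row['name']}")
            if lig in ligand_index:
                raise ValueError(
                    f"duplicate ligand code {lig} across classes "
                    f"({ligand_index[lig]}, {row['name']})"
                )
            ligand_index[lig] = row["name"]
        classes[row["name"]] = CoenzymeClassRecord(
            class_name=row["name"],
            temporality=temp,
            nucleotide_derived=bool(row.get("nucleotide_derived", False)),
            phosphate_containing=bool(row.get("phosphate_containing", False)),
            member_ligand_codes=ligs,
            excluded=bool(row.get("excluded", False)),
        )
    reg = Registry(
        amino_acids=aas,
        coenzyme_classes=classes,
        _one_letter_index=one_letter,
        _ligand_index=ligand_index,
    )
    reg.validate()
    return reg


def load_registry(config_path: str | Path | None = None) -> Registry:
    """Load the registry from a YAML config; defaults to the packaged table."""
    if config_path is None:
        text = (
            resources.files("coenzsites").joinpath("data/registry.yaml")
            .read_text()
        )
    else:
        text = Path(config_path).read_text()
    return _parse_registry(yaml.safe_load(text))


def canonical_yaml(reg: Registry) -> str:
    """Render a registry in the canonical config layout (stable byte-wise)."""
    lines = ["schema: 1", "amino_acids:"]
    for rec in sorted(reg.amino_acids.values(), key=lambda r: r.chronology_rank):
        lines.append(
            f"- {{three: {rec.three_letter_code}, one: {rec.one_letter_code}, "
            f"era: {rec.era.value}, rank: {rec.chronology_rank}}}"
        )
    lines.append("coenzyme_classes:")
    for rec in sorted(reg.coenzyme_classes.values(), key=lambda r: r.class_name):
        lines.append(f"- name: {rec.class_name}")
        lines.append(f"  temporality: {rec.temporality.value}")
        lines.append(
            f"  nucleotide_derived: {str(rec.nucleotide_derived).lower()}"
        )
        lines.append(
            f"  phosphate_containing: {str(rec.phosphate_containing).lower()}"
        )
        if rec.excluded:
            lines.append("  excluded: true")
        ligs = ", ".join(sorted(rec.member_ligand_codes))
        lines.append(f"  ligands: [{ligs}]")
    return "\n".join(lines) + "\n"


def dump_registry(reg: Registry, path: str | Path) -> None:
    Path(path).write_text(canonical_yaml(reg))
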