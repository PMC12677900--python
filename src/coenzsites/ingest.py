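"""Input readers and redundancy removal.

Three kinds of input are consumed here:

* per-structure residue-ligand contact records (JSON; the label vocabulary
  follows the atomic-contact classifier used by the PDBe pipelines),
* residue-level structure-to-UniProt cross-reference maps (SIFTS-style TSV,
  either the range dialect of ``pdb_chain_uniprot.tsv`` or a per-residue
  dialect),
* protein sequences (FASTA).

Contacts are lifted from author numbering to UniProt coordinates, and
sequence redundancy is removed with a greedy, longest-first identity
clustering in the style of CD-HIT.  Identity between two sequences is
approximated as the maximum number of exact positional matches over all
ungapped relative offsets, divided by the length of the shorter sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .manifest import Manifest
from .registry import METAL_ELEMENTS

logger = logging.getLogger(__name__)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

STANDARD_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


@dataclass(frozen=True)
class ContactRecord:
    """One residue-atom <-> ligand contact observed in one structure."""

    structure_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    ligand_code: str
    ligand_instance: str
    raw_labels: tuple[str, ...]
    partner_is_metal: bool
    #: bound-molecule environment the partner belongs to; for coenzyme
    #: contacts this equals ``ligand_instance``, for metal-ion partners it
    #: names the coenzyme instance whose binding environment the ion shares.
    environment: str = ""

    @property
    def residue_key(self) -> str:
        return f"{self.residue_number}{self.insertion_code}"


@dataclass(frozen=True)
class LiftedContact:
    """A contact re-keyed to UniProt coordinates (structure id retained)."""

    uniprot_accession: str
    uniprot_position: int
    structure_id: str
    residue_name: str
    atom_name: str
    ligand_code: str
    ligand_instance: str
    raw_labels: tuple[str, ...]
    partner_is_metal: bool
    environment: str = ""


def parse_contact_entries(
    structure_id: str,
    entries: Sequence[dict],
    manifest: Manifest | None = None,
    source: str = "<memory>",
) -> list[ContactRecord]:
    """Validate raw contact dicts into :class:`ContactRecord` objects.

    Water contacts are dropped; non-standard residues are dropped (they are
    excluded from era statistics); metal-ion partners are retained with
    ``partner_is_metal`` set (derived from a curated metal-code table when
    the flag is absent).
    """
    manifest = manifest or Manifest()
    sec = manifest.section("contacts")
    records: list[ContactRecord] = []
    for raw in entries:
        sec.add_total()
        try:
            resname = str(raw["resname"]).upper()
            ligand = str(raw["ligand"]).upper()
            labels = tuple(str(x) for x in raw["labels"])
            if not labels:
                raise KeyError("labels")
            rec = ContactRecord(
                structure_id=structure_id,
                chain_id=str(raw["chain"]),
                residue_number=int(raw["resnum"]),
                insertion_code=str(raw.get("icode", "") or ""),
                residue_name=resname,
                atom_name=str(raw["atom"]).upper(),
                ligand_code=ligand,
                ligand_instance=str(raw["ligand_instance"]),
                raw_labels=labels,
                partner_is_metal=bool(
                    raw.get("partner_is_metal", ligand in METAL_ELEMENTS)
                ),
                environment=str(raw.get("environment", "")
                                or raw["ligand_instance"]),
            )
        except (KeyError, TypeError, ValueError):
            sec.drop("malformed")
            logger.warning("%s: skipping malformed contact record", source)
            continue
        if rec.residue_name in WATER_NAMES:
            sec.drop("water")
            continue
        if rec.residue_name not in STANDARD_RESIDUES:
            sec.drop("nonstandard_residue")
            continue
        records.append(rec)
    return records


def read_contacts(
    path: str | Path, manifest: Manifest | None = None
) -> list[ContactRecord]:
    """Read one structure's contact records from a JSON file.

    See :func:`parse_contact_entries` for the filtering rules.  Raises
    ``ValueError`` if the schema version is absent or no valid record
    remains.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != 1:
        raise ValueError(f"{path}: missing or unsupported schema version")
    records = parse_contact_entries(
        doc["structure_id"], doc.get("contacts", []), manifest, source=str(path)
    )
    if not records:
        raise ValueError(f"{path}: no valid contact records")
    return records


def read_contact_dir(
    directory: str | Path, manifest: Manifest | None = None
) -> list[ContactRecord]:
    """Read every ``*.json`` contact file in a directory (sorted order)."""
    records: list[ContactRecord] = []
    for p in sorted(Path(directory).glob("*.json")):
        records.extend(read_contacts(p, manifest))
    return records


# ---------------------------------------------------------------------------
# SIFTS-style residue maps


class SiftsResidueMap:
    """Functional map (structure, chain, residue-key) -> (accession, position).

    Residue keys concatenate author numbering with any insertion code
    (e.g. ``"100A"``).  Structure residues that map to more than one UniProt
    position are ambiguous (chimeric chains) and removed entirely.
    """

    def __init__(self) -> None:
        self._map: dict[tuple[str, str, str], tuple[str, int]] = {}
        self._ambiguous: set[tuple[str, str, str]] = set()
        self.n_ambiguous_dropped = 0

    def add(
        self, structure_id: str, chain_id: str, residue_key: str,
        accession: str, position: int,
    ) -> None:
        key = (structure_id, chain_id, residue_key)
        if key in self._ambiguous:
            return
        existing = self._map.get(key)
        if existing is not None and existing != (accession, position):
            del self._map[key]
            self._ambiguous.add(key)
            self.n_ambiguous_dropped += 1
            return
        self._map[key] = (accession, position)

    def get(
        self, structure_id: str, chain_id: str, residue_key: str
    ) -> tuple[str, int] | None:
        return self._map.get((structure_id, chain_id, residue_key))

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def reverse(self) -> dict[tuple[str, int], list[tuple[str, str, str]]]:
        """(accession, position) -> list of structure residues mapping to it."""
        rev: dict[tuple[str, int], list[tuple[str, str, str]]] = {}
        for key, val in self._map.items():
            rev.setdefault(val, []).append(key)
        for lst in rev.values():
            lst.sort()
        return rev

    def structures_of(self, accession: str) -> set[str]:
        return {
            k[0] for k, v in self._map.items() if v[0] == accession
        }


_RANGE_HEADER = [
    "PDB", "CHAIN", "SP_PRIMARY", "RES_BEG", "RES_END",
    "PDB_BEG", "PDB_END", "SP_BEG", "SP_END",
]


def read_sifts_tsv(path: str | Path) -> SiftsResidueMap:
    """Read the range dialect of ``pdb_chain_uniprot.tsv``.

    Range rows are expanded to per-residue entries.  Rows whose author
    numbering is non-numeric (insertion-coded ranges) cannot be expanded
    and are skipped with a warning.
    """
    smap = SiftsResidueMap()
    lines = Path(path).read_text().splitlines()
    header_seen = False
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            if [f.strip().upper() for f in fields] != _RANGE_HEADER:
                raise ValueError(f"{path}: unexpected SIFTS header: {fields}")
            header_seen = True
            continue
        pdb, chain, acc = fields[0], fields[1], fields[2]
        try:
            pdb_beg, pdb_end = int(fields[5]), int(fields[6])
            sp_beg, sp_end = int(fields[7]), int(fields[8])
        except ValueError:
            logger.warning("%s: cannot expand non-numeric range row", path)
            continue
        if pdb_end - pdb_beg != sp_end - sp_beg:
            logger.warning("%s: skewed range row for %s/%s", path, pdb, chain)
            continue
        for offset in range(pdb_end - pdb_beg + 1):
            smap.add(pdb, chain, str(pdb_beg + offset), acc, sp_beg + offset)
    return smap


def read_residue_map_tsv(path: str | Path) -> SiftsResidueMap:
    """Read the per-residue dialect: ``PDB CHAIN PDB_RES SP_PRIMARY SP_RES``.

    ``PDB_RES`` may carry an insertion code suffix (``"100A"``).
    """
    smap = SiftsResidueMap()
    lines = Path(path).read_text().splitlines()
    header = [
        f.strip().upper() for f in lines[0].split("\t")
    ] if lines else []
    if header != ["PDB", "CHAIN", "PDB_RES", "SP_PRIMARY", "SP_RES"]:
        raise ValueError(f"{path}: unexpected per-residue header: {header}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        pdb, chain, reskey, acc, pos = line.rstrip("\n").split("\t")
        smap.add(pdb, chain, reskey, acc, int(pos))
    return smap


def lift_to_uniprot(
    contacts: Sequence[ContactRecord],
    smap: SiftsResidueMap,
    manifest: Manifest | None = None,
) -> list[LiftedContact]:
    """Re-key structure-level contacts to (accession, UniProt position).

    Contacts without a mapping are dropped and counted; an entirely
    unmappable input is an error.
    """
    if len(smap) == 0:
        raise ValueError("empty residue map")
    manifest = manifest or Manifest()
    sec = manifest.section("contacts")
    lifted: list[LiftedContact] = []
    n_unmapped = 0
    for rec in contacts:
        hit = smap.get(rec.structure_id, rec.chain_id, rec.residue_key)
        if hit is None:
            sec.drop("unmapped")
            n_unmapped += 1
            continue
        acc, pos = hit
        lifted.append(LiftedContact(
            uniprot_accession=acc,
            uniprot_position=pos,
            structure_id=rec.structure_id,
            residue_name=rec.residue_name,
            atom_name=rec.atom_name,
            ligand_code=rec.ligand_code,
            ligand_instance=rec.ligand_instance,
            raw_labels=rec.raw_labels,
            partner_is_metal=rec.partner_is_metal,
            environment=rec.environment,
        ))
    if contacts and not lifted:
        raise ValueError("no contact could be lifted to UniProt coordinates")
    if n_unmapped:
        logger.info("dropped %d unmapped contacts", n_unmapped)
    return lifted


# ---------------------------------------------------------------------------
# Sequence reading and identity clustering


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences into {accession: sequence} (order preserved)."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


@dataclass(frozen=True)
class ClusterAssignment:
    representative: str
    members: frozenset[str]
    threshold: float


def sequence_identity(a: str, b: str) -> Fraction:
    """Ungapped identity: max matches over all offsets / len of shorter.

    This is a deliberate, documented approximation of the global identity
    used by external clustering tools; it is exact for equal-length
    sequences differing only by substitutions.
    """
    if not a or not b:
        return Fraction(0)
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    if len(xa) < len(xb):
        xa, xb = xb, xa
    la, lb = len(xa), len(xb)
    best = 0
    # slide the shorter sequence across every overlapping offset
    for shift in range(-(lb - 1), la):
        a_lo, a_hi = max(0, shift), min(la, shift + lb)
        if a_hi - a_lo <= best:
            continue
        b_lo = a_lo - shift
        matches = int(
            np.count_nonzero(xa[a_lo:a_hi] == xb[b_lo:b_lo + (a_hi - a_lo)])
        )
        if matches > best:
            best = matches
    return Fraction(best, lb)


def cluster_sequences(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    threshold: float = 0.9,
) -> list[ClusterAssignment]:
    """Greedy longest-first identity clustering (CD-HIT style).

    Sequences are sorted by length (descending), ties broken by accession;
    each sequence joins the first existing representative it matches at
    ``identity >= threshold``, otherwise it founds a new cluster.  The
    representative is therefore always the longest member.  Deterministic
    for a given input set.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = list(
        sequences.items() if isinstance(sequences, Mapping) else sequences
    )
    if not items:
        raise ValueError("no sequences to cluster")
    th = Fraction(threshold).limit_denominator(10**6)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str, frozenset[str]]] = []
    members: dict[str, list[str]] = {}
    singletons: list[tuple[str, str]] = []
    for acc, seq in items:
        lb = len(seq)
        if lb < 10:
            # too short for a meaningful identity: forced singleton
            logger.warning(
                "sequence %s shorter than 10 residues; kept as singleton",
                acc,
            )
            singletons.append((acc, seq))
            continue
        windows = [seq[i:i + 5] for i in range(lb - 4)]
        # short-word screen: at identity >= th the best ungapped alignment
        # has >= ceil(th*lb) matches, hence at least
        # ceil(th*lb) - 4 - 5*(lb - ceil(th*lb)) of this sequence's 5-mers
        # occur verbatim in the representative.  The bound is conservative:
        # it can only skip pairs that the full scan would reject anyway.
        mt = -((-th.numerator * lb) // th.denominator)
        min_shared = mt - 4 - 5 * (lb - mt)
        home = None
        for racc, rseq, rkmers in reps:
            if windows and min_shared > 0:
                if sum(w in rkmers for w in windows) < min_shared:
                    continue
            if sequence_identity(seq, rseq) >= th:
                home = racc
                break
        if home is None:
            reps.append((acc, seq, frozenset(windows)))
            members[acc] = [acc]
        else:
            members[home].append(acc)
    return [
        ClusterAssignment(racc, frozenset(members[racc]), threshold)
        for racc, _, _ in reps
    ] + [
        ClusterAssignment(acc, frozenset({acc}), threshold)
        for acc, _ in singletons
    ]


def representatives(clusters: Sequence[ClusterAssignment]) -> frozenset[str]:
    return frozenset(c.representative for c in clusters)
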