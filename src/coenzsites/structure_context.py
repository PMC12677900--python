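"""Structural context of binding sites.

Covers four analyses:

* secondary-structure content of site residues, with per-residue redundancy
  removal: for each UniProt position, the *set* of codes ({h: helix,
  b: strand, c: coil}) observed across all structures of the protein is
  kept, so a position seen as helix in every structure contributes one
  helix observation, while a position seen as both helix and coil
  contributes to both bins;
* fold diversity: the number of distinct ECOD X-groups whose domains
  contain at least one site residue, per coenzyme class;
* exclusive-site detection: sites of >= 2 residues bound entirely by early
  (or entirely by late) amino acids;
* conservation summaries over exclusive sites: the fraction of residues
  with conservation grade >= 7 and the fraction identical to the most
  frequent residue of the homolog alignment (MAX AA).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .binding_sites import BindingSite
from .composition_stats import TEMPORALITY_ORDER
from .ingest import SiftsResidueMap
from .manifest import Manifest
from .registry import Era, Registry

logger = logging.getLogger(__name__)

SS_CODES = ("h", "b", "c")

#: DSSP-style alphabet collapsed onto the 3-code convention.
DSSP_TO_HBC = {
    "H": "h", "G": "h", "I": "h", "P": "h",
    "E": "b", "B": "b",
    "T": "c", "S": "c", "C": "c", "-": "c", " ": "c",
}


def collapse_ss_code(code: str) -> str:
    """Map a raw secondary-structure code onto {h, b, c}."""
    if code in SS_CODES:
        return code
    try:
        return DSSP_TO_HBC[code.upper()]
    except KeyError:
        raise ValueError(f"unknown secondary-structure code {code!r}") from None


class SecondaryStructureAssignment:
    """(structure, chain, residue-key) -> code in {h, b, c}."""

    def __init__(self) -> None:
        self._map: dict[tuple[str, str, str], str] = {}

    def add(
        self, structure_id: str, chain_id: str, residue_key: str, code: str
    ) -> None:
        self._map[(structure_id, chain_id, residue_key)] = collapse_ss_code(code)

    def get(
        self, structure_id: str, chain_id: str, residue_key: str
    ) -> str | None:
        return self._map.get((structure_id, chain_id, residue_key))

    def __len__(self) -> int:
        return len(self._map)


def read_ss_tsv(path: str | Path) -> SecondaryStructureAssignment:
    """Read ``PDB CHAIN PDB_RES SS`` rows (tab-separated, with header)."""
    ss = SecondaryStructureAssignment()
    lines = Path(path).read_text().splitlines()
    header = [f.strip().upper() for f in lines[0].split("\t")] if lines else []
    if header != ["PDB", "CHAIN", "PDB_RES", "SS"]:
        raise ValueError(f"{path}: unexpected SS header: {header}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        pdb, chain, reskey, code = line.rstrip("\n").split("\t")
        ss.add(pdb, chain, reskey, code)
    return ss


def residue_ss_profile(
    accession: str,
    position: int,
    ss: SecondaryStructureAssignment,
    reverse_map: Mapping[tuple[str, int], list[tuple[str, str, str]]],
) -> frozenset[str]:
    """Set of secondary-structure codes observed for one UniProt position.

    The set (not multiset) across all structures of the protein implements
    per-residue redundancy removal.  An unobserved residue yields an empty
    set and is excluded from content statistics by the caller.
    """
    codes = set()
    for structure_id, chain_id, reskey in reverse_map.get(
        (accession, position), ()
    ):
        code = ss.get(structure_id, chain_id, reskey)
        if code is not None:
            codes.add(code)
    return frozenset(codes)


def annotate_ss_profiles(
    sites: Sequence[BindingSite],
    ss: SecondaryStructureAssignment,
    smap: SiftsResidueMap,
    manifest: Manifest | None = None,
) -> None:
    """Fill each site's per-residue secondary-structure profile in place."""
    manifest = manifest or Manifest()
    sec = manifest.section("ss_residues")
    rev = smap.reverse()
    for site in sites:
        profile: dict[int, frozenset[str]] = {}
        for res in site.residues:
            sec.add_total()
            codes = residue_ss_profile(
                site.uniprot_accession, res.uniprot_position, ss, rev
            )
            profile[res.uniprot_position] = codes
            if codes:
                sec.use("observed")
            else:
                sec.drop("ss_unobserved")
        site.secondary_structure_profile = profile


def ss_content(
    sites: Sequence[BindingSite],
    ss: SecondaryStructureAssignment,
    smap: SiftsResidueMap,
) -> pd.DataFrame:
    """Secondary-structure composition of site residues per temporality.

    Counting is over (residue, code) pairs after per-residue redundancy
    removal, so multi-code profiles contribute to every code they contain.
    A dataset-wide background row ("background") covers every mapped
    residue with an observed code, site or not.
    """
    rev = smap.reverse()
    counts: dict[str, Counter] = defaultdict(Counter)
    for site in sites:
        t = site.temporality.value
        profile = site.secondary_structure_profile
        for res in site.residues:
            codes = profile.get(res.uniprot_position)
            if codes is None:
                codes = residue_ss_profile(
                    site.uniprot_accession, res.uniprot_position, ss, rev
                )
            for code in codes:
                counts[t][code] += 1
    # background: every mapped uniprot residue with at least one observation
    bg = Counter()
    for (acc, pos), keys in rev.items():
        codes = {
            ss.get(*key) for key in keys
        } - {None}
        for code in codes:
            bg[code] += 1
    rows = []
    order = [t.value for t in TEMPORALITY_ORDER if t.value in counts]
    for name, counter in [(t, counts[t]) for t in order] + [("background", bg)]:
        total = sum(counter.values())
        if total == 0:
            logger.warning("no observed secondary structure for %s", name)
            continue
        row = {"group": name, "n_pairs": total}
        for code in SS_CODES:
            row[f"{code}_pct"] = 100.0 * counter[code] / total
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# ECOD fold diversity


@dataclass(frozen=True)
class EcodDomain:
    domain_id: str
    structure_id: str
    chain_id: str
    res_start: int
    res_end: int
    x_group: str
    h_group: str = ""
    f_group: str = ""


class EcodTable:
    def __init__(self, domains: Sequence[EcodDomain] = ()) -> None:
        self._by_chain: dict[tuple[str, str], list[EcodDomain]] = defaultdict(
            list
        )
        for d in domains:
            self.add(d)

    def add(self, domain: EcodDomain) -> None:
        if not domain.x_group:
            raise ValueError(f"domain {domain.domain_id}: empty X-group")
        if domain.res_end < domain.res_start:
            raise ValueError(f"domain {domain.domain_id}: inverted range")
        self._by_chain[(domain.structure_id, domain.chain_id)].append(domain)

    def x_groups_at(
        self, structure_id: str, chain_id: str, residue_number: int
    ) -> set[str]:
        return {
            d.x_group
            for d in self._by_chain.get((structure_id, chain_id), ())
            if d.res_start <= residue_number <= d.res_end
        }

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chain.values())


def read_ecod_tsv(path: str | Path) -> EcodTable:
    """Read the flat dialect: ``DOMAIN PDB CHAIN RES_BEG RES_END X H F``."""
    table = EcodTable()
    lines = Path(path).read_text().splitlines()
    header = [f.strip().upper() for f in lines[0].split("\t")] if lines else []
    if header != ["DOMAIN", "PDB", "CHAIN", "RES_BEG", "RES_END", "X", "H", "F"]:
        raise ValueError(f"{path}: unexpected ECOD header: {header}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        dom, pdb, chain, beg, end, x, h, f = line.rstrip("\n").split("\t")
        table.add(EcodDomain(dom, pdb, chain, int(beg), int(end), x, h, f))
    return table


def _residue_key_number(residue_key: str) -> int:
    """Strip any insertion-code suffix from a residue key."""
    digits = residue_key
    while digits and not digits[-1].isdigit():
        digits = digits[:-1]
    return int(digits)


def fold_diversity(
    sites: Sequence[BindingSite],
    ecod: EcodTable,
    smap: SiftsResidueMap,
) -> pd.DataFrame:
    """Distinct ECOD X-group and protein counts per coenzyme class.

    A site contributes an X-group when at least one of its residues lies,
    in any structure of the protein, inside a domain of that group.
    Duplicating a structure of an already-counted protein cannot change the
    result (X-groups are collected as a set).
    """
    rev = smap.reverse()
    class_groups: dict[str, set[str]] = defaultdict(set)
    class_proteins: dict[str, set[str]] = defaultdict(set)
    for site in sites:
        class_proteins[site.coenzyme_class].add(site.uniprot_accession)
        for res in site.residues:
            for structure_id, chain_id, reskey in rev.get(
                (site.uniprot_accession, res.uniprot_position), ()
            ):
                groups = ecod.x_groups_at(
                    structure_id, chain_id, _residue_key_number(reskey)
                )
                class_groups[site.coenzyme_class].update(groups)
    rows = []
    for cls in sorted(class_proteins):
        n_groups = len(class_groups[cls])
        if n_groups == 0:
            logger.warning("coenzyme class %s has no ECOD coverage", cls)
        rows.append({
            "coenzyme_class": cls,
            "n_x_groups": n_groups,
            "n_proteins": len(class_proteins[cls]),
        })
    return pd.DataFrame(
        rows, columns=["coenzyme_class", "n_x_groups", "n_proteins"]
    ).set_index("coenzyme_class")


# ---------------------------------------------------------------------------
# Exclusive sites and conservation


def find_exclusive_sites(
    sites: Sequence[BindingSite],
    registry: Registry,
    era: Era | str,
) -> list[BindingSite]:
    """Sites of >= 2 residues bound entirely by one era's amino acids."""
    era = Era(era)
    out = []
    for site in sites:
        if len(site.residues) < 2:
            continue
        if all(r.era is era for r in site.residues):
            out.append(site)
    return out


class ConservationTable:
    """(accession, position) -> (grade 1-9, most frequent residue)."""

    def __init__(self) -> None:
        self._map: dict[tuple[str, int], tuple[int, str]] = {}

    def add(
        self, accession: str, position: int, grade: int, max_aa: str
    ) -> None:
        if not 1 <= grade <= 9:
            raise ValueError(f"conservation grade must be 1..9, got {grade}")
        self._map[(accession, position)] = (grade, max_aa.upper())

    def get(self, accession: str, position: int) -> tuple[int, str] | None:
        return self._map.get((accession, position))

    def __len__(self) -> int:
        return len(self._map)


def read_conservation_tsv(path: str | Path) -> ConservationTable:
    """Read ``ACC POS GRADE MAX_AA`` rows (tab-separated, with header)."""
    table = ConservationTable()
    lines = Path(path).read_text().splitlines()
    header = [f.strip().upper() for f in lines[0].split("\t")] if lines else []
    if header != ["ACC", "POS", "GRADE", "MAX_AA"]:
        raise ValueError(f"{path}: unexpected conservation header: {header}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        acc, pos, grade, max_aa = line.rstrip("\n").split("\t")
        table.add(acc, int(pos), int(grade), max_aa)
    return table


@dataclass(frozen=True)
class ConservationSummary:
    n_residues_covered: int
    n_residues_uncovered: int
    n_grade_ge7: int
    n_max_aa_identical: int

    @property
    def fraction_grade_ge7(self) -> float:
        return self.n_grade_ge7 / self.n_residues_covered

    @property
    def fraction_max_aa_identical(self) -> float:
        return self.n_max_aa_identical / self.n_residues_covered

    def as_dict(self) -> dict:
        return {
            "n_residues_covered": self.n_residues_covered,
            "n_residues_uncovered": self.n_residues_uncovered,
            "n_grade_ge7": self.n_grade_ge7,
            "n_max_aa_identical": self.n_max_aa_identical,
            "fraction_grade_ge7": self.fraction_grade_ge7,
            "fraction_max_aa_identical": self.fraction_max_aa_identical,
        }


def conservation_summary(
    sites: Sequence[BindingSite],
    conservation: ConservationTable,
    registry: Registry,
) -> ConservationSummary:
    """Conservation of (typically exclusive) site residues.

    Reports the fraction of covered residues with grade >= 7 and the
    fraction whose identity equals the alignment's most frequent residue;
    residues without conservation coverage are excluded and counted.
    """
    covered = uncovered = ge7 = identical = 0
    for site in sites:
        for res in site.residues:
            hit = conservation.get(site.uniprot_accession, res.uniprot_position)
            if hit is None:
                uncovered += 1
                continue
            covered += 1
            grade, max_aa = hit
            if grade >= 7:
                ge7 += 1
            if len(max_aa) == 1:
                max_aa = registry.amino_acid(max_aa).three_letter_code
            if max_aa == res.residue_name:
                identical += 1
    if covered == 0:
        raise ValueError("no site residue has conservation coverage")
    return ConservationSummary(covered, uncovered, ge7, identical)
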