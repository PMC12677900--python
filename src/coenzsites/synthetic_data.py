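"""Synthetic input bundles with planted, recorded parameters.

The generator emulates the statistical shape of a structure-database survey
of coenzyme binding without simulating any 3D geometry: a set of proteins
per coenzyme temporality, each represented by several structures; a planted
consensus binding site per protein whose residues are drawn early-vs-late
with a per-temporality occupancy probability; stochastic per-structure
retention of site contacts (so interaction ratios are non-trivial);
backbone / side-chain / both contact modes (glycine sites are always
backbone-only, as glycine has no side-chain heavy atom); grouped
contact-type mixes; occasional clash-only records; metal-ion co-binding in
the coenzyme's bound-molecule environment; per-residue secondary-structure
codes; one ECOD domain per protein; and a simple conservation-grade model.

Every planted parameter, and every realized per-protein site definition,
is restated in a truth file so downstream estimates can be checked against
what was actually generated.  Generation is deterministic given the seed.

Default parameters echo the study conditions the pipeline is meant to
emulate: per-temporality early-residue occupancies of 0.61 / 0.53 / 0.47
(Ancient / LUCA / Post-LUCA), a 67% early background, backbone-only
fractions highest for Ancient sites (0.24), and metal-mediation
probabilities of 0.24 / 0.13 / 0.11 / 0.23.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .binding_sites import ContactMode
from .ingest import ContactRecord, SiftsResidueMap, parse_contact_entries
from .manifest import Manifest
from .registry import (
    BACKBONE_ATOMS,
    RAW_LABEL_GROUPS,
    SIDECHAIN_ATOMS,
    ContactGroup,
    Registry,
    Temporality,
    load_registry,
)

#: raw labels per grouped type, for drawing a concrete label within a group
_GROUP_LABELS: dict[ContactGroup, list[str]] = {}
for _label, _group in RAW_LABEL_GROUPS.items():
    _GROUP_LABELS.setdefault(_group, []).append(_label)
for _lst in _GROUP_LABELS.values():
    _lst.sort()

_EARLY = ["ALA", "ASP", "GLU", "GLY", "ILE", "LEU", "PRO", "SER", "THR", "VAL"]
_LATE = ["ARG", "ASN", "CYS", "GLN", "HIS", "LYS", "MET", "PHE", "TRP", "TYR"]
_EARLY_NO_GLY = [a for a in _EARLY if a != "GLY"]

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_EARLY_LETTERS = np.array([_ONE_LETTER[a] for a in _EARLY], dtype="U1")
_LATE_LETTERS = np.array([_ONE_LETTER[a] for a in _LATE], dtype="U1")


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


def _check_mix(name: str, mix: dict) -> None:
    if not mix:
        raise ValueError(f"{name} must be non-empty")
    for k, v in mix.items():
        if v < 0:
            raise ValueError(f"{name}[{k}] is negative")
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1, sums to {sum(mix.values())}")


@dataclass
class TemporalityBlock:
    """Planted parameters for one coenzyme temporality."""

    n_proteins: int = 200
    #: ("uniform", lo, hi) or ("fixed", n)
    structures_per_protein: tuple = ("uniform", 1, 3)
    #: ("poisson", mean, minimum) or ("fixed", n)
    site_size: tuple = ("poisson", 8.0, 2)
    early_occupancy: float = 0.5
    retention: float = 0.9
    #: (backbone_only, sidechain_only, both)
    mode_probs: tuple[float, float, float] = (0.15, 0.60, 0.25)
    grouped_type_mix: dict[str, float] = field(default_factory=lambda: dict(
        _DEFAULT_TYPE_MIX))
    clash_rate: float = 0.02
    metal_prob: float = 0.15
    metal_element_mix: dict[str, float] = field(default_factory=lambda: dict(
        _DEFAULT_METAL_MIX))
    ss_mix: dict[str, float] = field(default_factory=lambda: dict(
        _DEFAULT_SS_MIX))

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        law = self.structures_per_protein[0]
        if law not in ("uniform", "fixed"):
            raise ValueError(f"unknown structures-per-protein law {law!r}")
        law = self.site_size[0]
        if law not in ("poisson", "fixed"):
            raise ValueError(f"unknown site-size law {law!r}")
        _check_prob("early_occupancy", self.early_occupancy)
        _check_prob("retention", self.retention)
        _check_prob("clash_rate", self.clash_rate)
        _check_prob("metal_prob", self.metal_prob)
        if len(self.mode_probs) != 3:
            raise ValueError("mode_probs must have three entries")
        _check_mix("mode_probs", dict(zip("bsx", self.mode_probs)))
        _check_mix("grouped_type_mix", self.grouped_type_mix)
        _check_mix("metal_element_mix", self.metal_element_mix)
        _check_mix("ss_mix", self.ss_mix)
        if set(self.ss_mix) != {"h", "b", "c"}:
            raise ValueError("ss_mix keys must be exactly {h, b, c}")
        for g in self.grouped_type_mix:
            cg = ContactGroup(g)
            if cg is ContactGroup.CLASHES:
                raise ValueError("grouped_type_mix must not include clashes")


_DEFAULT_TYPE_MIX = {
    "electrostatic": 0.45, "vdw": 0.20, "hydrophobic": 0.15,
    "aromatic": 0.07, "atom-pi": 0.05, "amide": 0.04, "metal": 0.03,
    "covalent": 0.01,
}
_DEFAULT_METAL_MIX = {"MG": 0.55, "CA": 0.20, "MN": 0.12, "FE": 0.08,
                      "ZN": 0.05}
_DEFAULT_SS_MIX = {"h": 0.35, "b": 0.20, "c": 0.45}


@dataclass
class SimulationConfig:
    seed: int = 0
    blocks: dict[str, TemporalityBlock] = field(default_factory=dict)
    sequence_length: int = 160
    background_early: float = 0.67
    background_ss_mix: dict[str, float] = field(default_factory=lambda: dict(
        _DEFAULT_SS_MIX))
    #: conservation model for site residues
    site_grade_high_prob: float = 0.60
    max_aa_identity_prob: float = 0.75

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("at least one temporality block is required")
        for name, block in self.blocks.items():
            Temporality(name)
            block.validate()
        if self.sequence_length < 20:
            raise ValueError("sequence_length must be >= 20")
        _check_prob("background_early", self.background_early)
        _check_mix("background_ss_mix", self.background_ss_mix)
        _check_prob("site_grade_high_prob", self.site_grade_high_prob)
        _check_prob("max_aa_identity_prob", self.max_aa_identity_prob)


def default_config(seed: int = 0, n_proteins: int = 200) -> SimulationConfig:
    """The default study conditions (one block per temporality)."""
    return SimulationConfig(seed=seed, blocks={
        Temporality.ANCIENT.value: TemporalityBlock(
            n_proteins=n_proteins, early_occupancy=0.61,
            mode_probs=(0.24, 0.52, 0.24), metal_prob=0.24,
            ss_mix={"h": 0.30, "b": 0.25, "c": 0.45},
        ),
        Temporality.LUCA.value: TemporalityBlock(
            n_proteins=n_proteins, early_occupancy=0.53,
            mode_probs=(0.13, 0.61, 0.26), metal_prob=0.13,
            ss_mix={"h": 0.33, "b": 0.22, "c": 0.45},
        ),
        Temporality.POST_LUCA.value: TemporalityBlock(
            n_proteins=n_proteins, early_occupancy=0.47,
            mode_probs=(0.10, 0.64, 0.26), metal_prob=0.11,
            ss_mix={"h": 0.45, "b": 0.12, "c": 0.43},
        ),
        Temporality.UNCLASSIFIED.value: TemporalityBlock(
            n_proteins=max(10, n_proteins // 4), early_occupancy=0.50,
            mode_probs=(0.15, 0.60, 0.25), metal_prob=0.23,
            ss_mix={"h": 0.38, "b": 0.17, "c": 0.45},
        ),
    })


@dataclass
class Bundle:
    """In-memory synthetic input bundle (files are an optional rendering)."""

    sequences: dict[str, str]
    #: structure_id -> list of raw contact dicts (the JSON schema's rows)
    contacts_by_structure: dict[str, list[dict]]
    #: rows of the per-residue SIFTS dialect
    sifts_rows: list[tuple[str, str, str, str, int]]
    ss_rows: list[tuple[str, str, str, str]]
    ecod_rows: list[tuple[str, str, str, int, int, str, str, str]]
    conservation_rows: list[tuple[str, int, int, str]]
    truth: dict

    def sifts_map(self) -> SiftsResidueMap:
        # fast path: generated rows are unique by construction, so the
        # per-row ambiguity bookkeeping of SiftsResidueMap.add is skipped
        smap = SiftsResidueMap()
        smap._map = {
            (pdb, chain, reskey): (acc, pos)
            for pdb, chain, reskey, acc, pos in self.sifts_rows
        }
        return smap

    def contact_records(
        self, manifest: Manifest | None = None
    ) -> list[ContactRecord]:
        records: list[ContactRecord] = []
        for sid in sorted(self.contacts_by_structure):
            records.extend(parse_contact_entries(
                sid, self.contacts_by_structure[sid], manifest, source=sid
            ))
        return records


def _draw_count(rng: np.random.Generator, law: tuple) -> int:
    if law[0] == "fixed":
        return int(law[1])
    if law[0] == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    if law[0] == "poisson":
        _, mean, minimum = law
        return max(int(minimum), int(rng.poisson(mean)))
    raise ValueError(f"unknown distribution law {law[0]!r}")


def _draw_mix(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def generate_bundle(
    config: SimulationConfig, registry: Registry | None = None
) -> Bundle:
    """Generate a complete synthetic bundle from planted parameters.

    Deterministic given ``config.seed``.  Raises before producing anything
    if the config is invalid.
    """
    config.validate()
    registry = registry or load_registry()
    rng = np.random.default_rng(config.seed)
    L = config.sequence_length

    sequences: dict[str, str] = {}
    contacts: dict[str, list[dict]] = {}
    sifts_rows: list[tuple[str, str, str, str, int]] = []
    ss_rows: list[tuple[str, str, str, str]] = []
    ecod_rows: list[tuple[str, str, str, int, int, str, str, str]] = []
    cons_rows: list[tuple[str, int, int, str]] = []
    truth_proteins: list[dict] = []

    structure_counter = 0
    acc_prefix = {
        Temporality.ANCIENT.value: "A",
        Temporality.LUCA.value: "L",
        Temporality.POST_LUCA.value: "Q",
        Temporality.UNCLASSIFIED.value: "U",
    }

    temp_order = [t.value for t in (
        Temporality.ANCIENT, Temporality.LUCA, Temporality.POST_LUCA,
        Temporality.UNCLASSIFIED,
    ) if t.value in config.blocks]

    bg_ss_keys = sorted(config.background_ss_mix)
    bg_ss_p = np.array(
        [config.background_ss_mix[k] for k in bg_ss_keys], dtype=float
    )
    bg_ss_p /= bg_ss_p.sum()

    for temp_name in temp_order:
        block = config.blocks[temp_name]
        classes = [
            c for c in registry.classes_of(Temporality(temp_name))
            if c.member_ligand_codes
        ]
        if not classes:
            raise ValueError(f"no usable coenzyme class for {temp_name}")
        classes.sort(key=lambda c: c.class_name)
        mode_p = np.array(block.mode_probs, dtype=float)
        mode_p /= mode_p.sum()
        group_keys = sorted(block.grouped_type_mix)
        group_p = np.array(
            [block.grouped_type_mix[k] for k in group_keys], dtype=float
        )
        group_p /= group_p.sum()
        ss_keys = sorted(block.ss_mix)
        ss_p = np.array([block.ss_mix[k] for k in ss_keys], dtype=float)
        ss_p /= ss_p.sum()
        mode_values = (
            ContactMode.BACKBONE_ONLY.value, ContactMode.SIDECHAIN_ONLY.value,
            ContactMode.BOTH.value,
        )
        # metal mediation is planted by exact count (stratified), so the
        # realized per-temporality rate equals the nominal probability and
        # estimator error is attributable to the pipeline, not the draw
        n_metal = round(block.metal_prob * block.n_proteins)
        metal_flags = np.zeros(block.n_proteins, dtype=bool)
        metal_flags[:n_metal] = True
        rng.shuffle(metal_flags)
        for i in range(block.n_proteins):
            acc = f"{acc_prefix[temp_name]}{i:05d}"
            cls = classes[i % len(classes)]
            ligand = sorted(cls.member_ligand_codes)[0]
            coenz_instance = f"{ligand}_1"

            # --- plant the site -------------------------------------------
            size = min(_draw_count(rng, block.site_size), L // 4)
            positions = sorted(
                int(p) for p in
                rng.choice(np.arange(1, L + 1), size=size, replace=False)
            )
            mode_draws = rng.choice(3, size=size, p=mode_p)
            early_draws = rng.random(size) < block.early_occupancy
            pool_picks = rng.random(size)
            residues: list[str] = []
            modes: list[str] = []
            for k in range(size):
                mode = mode_values[int(mode_draws[k])]
                if early_draws[k]:
                    pool = (
                        _EARLY if mode == ContactMode.BACKBONE_ONLY.value
                        else _EARLY_NO_GLY
                    )
                else:
                    pool = _LATE
                residues.append(pool[int(pool_picks[k] * len(pool))])
                modes.append(mode)
            # one grouped interaction type per site residue
            groups = [
                group_keys[j] for j in rng.choice(len(group_keys), size=size,
                                                  p=group_p)
            ]
            ss_codes = [
                ss_keys[j] for j in rng.choice(len(ss_keys), size=size, p=ss_p)
            ]
            metal_element = (
                _draw_mix(rng, block.metal_element_mix)
                if metal_flags[i] else None
            )

            # --- sequence and per-position secondary structure ------------
            early_bg = rng.random(L) < config.background_early
            aa_picks = rng.integers(10, size=L)
            bg_ss_draws = rng.choice(len(bg_ss_keys), size=L, p=bg_ss_p)
            letters = np.where(
                early_bg, _EARLY_LETTERS[aa_picks], _LATE_LETTERS[aa_picks]
            )
            ss_arr = np.array(bg_ss_keys, dtype="U1")[bg_ss_draws]
            for k, pos in enumerate(positions):
                letters[pos - 1] = _ONE_LETTER[residues[k]]
                ss_arr[pos - 1] = ss_codes[k]
            sequences[acc] = "".join(letters)
            ss_all = ss_arr.tolist()

            # --- structures ------------------------------------------------
            n_structures = _draw_count(rng, block.structures_per_protein)
            x_group = f"X.{1 + i % len(classes)}.{1 + int(rng.integers(5))}"
            structure_ids = []
            for _s in range(n_structures):
                sid = f"{structure_counter:04d}"
                structure_counter += 1
                structure_ids.append(sid)
                offset = int(rng.choice([0, 100]))
                chain = "A"
                author_keys = [str(pos + offset) for pos in range(1, L + 1)]
                sifts_rows.extend(zip(
                    (sid,) * L, (chain,) * L, author_keys,
                    (acc,) * L, range(1, L + 1),
                ))
                ss_rows.extend(zip(
                    (sid,) * L, (chain,) * L, author_keys, ss_all,
                ))
                ecod_rows.append((
                    f"e{sid}{chain}1", sid, chain, 1 + offset, L + offset,
                    x_group, f"{x_group}.H", f"{x_group}.F",
                ))
                entries: list[dict] = []
                any_present = False
                for k, pos in enumerate(positions):
                    if rng.random() >= block.retention:
                        continue
                    any_present = True
                    res = residues[k]
                    mode = modes[k]
                    if mode == ContactMode.BACKBONE_ONLY.value:
                        atom_pool = sorted(BACKBONE_ATOMS)
                        atoms = [atom_pool[int(rng.integers(len(atom_pool)))]]
                    elif mode == ContactMode.SIDECHAIN_ONLY.value:
                        atom_pool = sorted(SIDECHAIN_ATOMS[res])
                        atoms = [atom_pool[int(rng.integers(len(atom_pool)))]]
                    else:
                        bb = sorted(BACKBONE_ATOMS)
                        sc = sorted(SIDECHAIN_ATOMS[res])
                        atoms = [
                            bb[int(rng.integers(len(bb)))],
                            sc[int(rng.integers(len(sc)))],
                        ]
                    labels_pool = _GROUP_LABELS[ContactGroup(groups[k])]
                    label = labels_pool[int(rng.integers(len(labels_pool)))]
                    for atom in atoms:
                        entries.append({
                            "chain": chain, "resnum": pos + offset,
                            "icode": "", "resname": res, "atom": atom,
                            "ligand": ligand,
                            "ligand_instance": coenz_instance,
                            "labels": [label],
                        })
                    if rng.random() < block.clash_rate:
                        entries.append({
                            "chain": chain, "resnum": pos + offset,
                            "icode": "", "resname": res, "atom": atoms[0],
                            "ligand": ligand,
                            "ligand_instance": coenz_instance,
                            "labels": ["vdw_clash"],
                        })
                if metal_element is not None and any_present:
                    k0 = positions.index(
                        min(p for p in positions)
                    )
                    entries.append({
                        "chain": chain,
                        "resnum": positions[k0] + offset,
                        "icode": "", "resname": residues[k0],
                        "atom": "CA" if modes[k0] ==
                        ContactMode.BACKBONE_ONLY.value
                        else sorted(SIDECHAIN_ATOMS[residues[k0]]
                                    or BACKBONE_ATOMS)[0],
                        "ligand": metal_element,
                        "ligand_instance": f"{metal_element}_1",
                        "labels": ["metal"],
                        "environment": coenz_instance,
                    })
                # a structure in which no site residue was retained has no
                # ligand contacts, hence no contact dump at all
                if entries:
                    contacts[sid] = entries

            # --- conservation ---------------------------------------------
            for k, pos in enumerate(positions):
                if rng.random() < config.site_grade_high_prob:
                    grade = 7 + int(rng.integers(3))
                else:
                    grade = 1 + int(rng.integers(6))
                if rng.random() < config.max_aa_identity_prob:
                    max_aa = _ONE_LETTER[residues[k]]
                else:
                    others = [
                        a for a in _ONE_LETTER.values()
                        if a != _ONE_LETTER[residues[k]]
                    ]
                    max_aa = others[int(rng.integers(len(others)))]
                cons_rows.append((acc, pos, grade, max_aa))

            truth_proteins.append({
                "accession": acc,
                "temporality": temp_name,
                "coenzyme_class": cls.class_name,
                "ligand": ligand,
                "n_structures": n_structures,
                "structure_ids": structure_ids,
                "site_positions": positions,
                "site_residues": residues,
                "site_modes": modes,
                "site_groups": groups,
                "site_ss": ss_codes,
                "metal_element": metal_element,
                "x_group": x_group,
            })

    truth = {
        "config": {
            "seed": config.seed,
            "sequence_length": config.sequence_length,
            "background_early": config.background_early,
            "background_ss_mix": config.background_ss_mix,
            "site_grade_high_prob": config.site_grade_high_prob,
            "max_aa_identity_prob": config.max_aa_identity_prob,
            "blocks": {k: asdict(v) for k, v in config.blocks.items()},
        },
        "proteins": truth_proteins,
    }
    return Bundle(
        sequences=sequences,
        contacts_by_structure=contacts,
        sifts_rows=sifts_rows,
        ss_rows=ss_rows,
        ecod_rows=ecod_rows,
        conservation_rows=cons_rows,
        truth=truth,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Render a bundle to its on-disk file formats (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "sequences.fasta", "w") as fh:
        for acc in sorted(bundle.sequences):
            fh.write(f">{acc}\n{bundle.sequences[acc]}\n")
    with open(outdir / "sifts.tsv", "w") as fh:
        fh.write("PDB\tCHAIN\tPDB_RES\tSP_PRIMARY\tSP_RES\n")
        for row in bundle.sifts_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(outdir / "ss.tsv", "w") as fh:
        fh.write("PDB\tCHAIN\tPDB_RES\tSS\n")
        for row in bundle.ss_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(outdir / "ecod.tsv", "w") as fh:
        fh.write("DOMAIN\tPDB\tCHAIN\tRES_BEG\tRES_END\tX\tH\tF\n")
        for row in bundle.ecod_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(outdir / "conservation.tsv", "w") as fh:
        fh.write("ACC\tPOS\tGRADE\tMAX_AA\n")
        for row in bundle.conservation_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    contacts_dir = outdir / "contacts"
    contacts_dir.mkdir(exist_ok=True)
    for sid in sorted(bundle.contacts_by_structure):
        doc = {
            "schema": 1,
            "structure_id": sid,
            "contacts": bundle.contacts_by_structure[sid],
        }
        (contacts_dir / f"{sid}.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n"
        )
    (outdir / "truth.json").write_text(
        json.dumps(bundle.truth, indent=1, sort_keys=True) + "\n"
    )


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    registry: Registry | None = None,
) -> Bundle:
    """Generate a bundle and write it under ``outdir``."""
    bundle = generate_bundle(config, registry)
    write_bundle(bundle, outdir)
    return bundle


# ---------------------------------------------------------------------------
# Minimal hand-written fixture


def make_minimal_fixture(outdir: str | Path | None = None) -> tuple[Bundle, dict]:
    """A tiny hand-written bundle (3 proteins, 2 coenzyme classes).

    Every expected downstream output is hand-computable; the returned dict
    freezes those expectations:

    * ``P10001`` (NAD, structures 9aaa/9aab): Gly12 backbone in both
      structures (ratio 1), Asp40 side chain in 9aaa only (ratio 1/2),
      Arg55 side chain in both (ratio 1).  Structure 9aab numbers its
      residues with a +100 author offset.
    * ``P10002`` (NAD, structure 9aac): Gly10 + Ser20, both early — a
      planted early-exclusive site — with one MG ion in the NAD
      environment.
    * ``P10003`` (Ascorbic acid, structure 9aad): a singleton Gly30 site
      (too small for the exclusive-site filter).

    Structure 9aaa also carries one water contact, one selenomethionine
    contact and one clash-only record, all of which must be dropped.
    """
    seq1 = list("A" * 60)
    seq1[11], seq1[39], seq1[54] = "G", "D", "R"
    seq2 = list("V" * 40)
    seq2[9], seq2[19] = "G", "S"
    seq3 = list("L" * 40)
    seq3[29] = "G"
    sequences = {
        "P10001": "".join(seq1),
        "P10002": "".join(seq2),
        "P10003": "".join(seq3),
    }
    contacts = {
        "9aaa": [
            {"chain": "A", "resnum": 12, "icode": "", "resname": "GLY",
             "atom": "N", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["hbond"]},
            {"chain": "A", "resnum": 40, "icode": "", "resname": "ASP",
             "atom": "OD1", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["ionic"]},
            {"chain": "A", "resnum": 55, "icode": "", "resname": "ARG",
             "atom": "NH1", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["ionic", "hbond"]},
            # dropped inputs: water, non-standard residue, clash-only
            {"chain": "A", "resnum": 201, "icode": "", "resname": "HOH",
             "atom": "O", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["hbond"]},
            {"chain": "A", "resnum": 7, "icode": "", "resname": "MSE",
             "atom": "SE", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["vdw"]},
            {"chain": "A", "resnum": 12, "icode": "", "resname": "GLY",
             "atom": "CA", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["vdw_clash"]},
        ],
        "9aab": [
            {"chain": "A", "resnum": 112, "icode": "", "resname": "GLY",
             "atom": "N", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["hbond"]},
            {"chain": "A", "resnum": 155, "icode": "", "resname": "ARG",
             "atom": "NH2", "ligand": "NAD", "ligand_instance": "NAD_1",
             "labels": ["CATIONPI"]},
        ],
        "9aac": [
            {"chain": "A", "resnum": 10, "icode": "", "resname": "GLY",
             "atom": "N", "ligand": "NAI", "ligand_instance": "NAI_1",
             "labels": ["hbond"]},
            {"chain": "A", "resnum": 20, "icode": "", "resname": "SER",
             "atom": "OG", "ligand": "NAI", "ligand_instance": "NAI_1",
             "labels": ["hbond", "vdw"]},
            {"chain": "A", "resnum": 20, "icode": "", "resname": "SER",
             "atom": "OG", "ligand": "MG", "ligand_instance": "MG_1",
             "labels": ["metal"], "environment": "NAI_1"},
        ],
        "9aad": [
            {"chain": "A", "resnum": 30, "icode": "", "resname": "GLY",
             "atom": "O", "ligand": "ASC", "ligand_instance": "ASC_1",
             "labels": ["weak_hbond"]},
        ],
    }
    sifts_rows = []
    for pos in range(1, 61):
        sifts_rows.append(("9aaa", "A", str(pos), "P10001", pos))
        sifts_rows.append(("9aab", "A", str(pos + 100), "P10001", pos))
    for pos in range(1, 41):
        sifts_rows.append(("9aac", "A", str(pos), "P10002", pos))
        sifts_rows.append(("9aad", "A", str(pos), "P10003", pos))
    ss_at = {
        ("9aaa", "12"): "h", ("9aaa", "40"): "c", ("9aaa", "55"): "h",
        ("9aab", "112"): "h", ("9aab", "155"): "c",
        ("9aac", "10"): "b", ("9aac", "20"): "b",
        ("9aad", "30"): "c",
    }
    ss_rows = []
    for pdb, chain, reskey, acc, pos in sifts_rows:
        code = ss_at.get((pdb, reskey), "c")
        ss_rows.append((pdb, chain, reskey, code))
    ecod_rows = [
        ("e9aaaA1", "9aaa", "A", 1, 60, "X.1", "X.1.H", "X.1.F"),
        ("e9aabA1", "9aab", "A", 101, 160, "X.1", "X.1.H", "X.1.F"),
        ("e9aacA1", "9aac", "A", 1, 40, "X.2", "X.2.H", "X.2.F"),
        ("e9aadA1", "9aad", "A", 1, 40, "X.3", "X.3.H", "X.3.F"),
    ]
    cons_rows = [
        ("P10002", 10, 8, "G"),
        ("P10002", 20, 7, "T"),
    ]
    truth = {"fixture": "minimal", "proteins": [
        {"accession": "P10001", "coenzyme_class": "NAD",
         "site_positions": [12, 40, 55]},
        {"accession": "P10002", "coenzyme_class": "NAD",
         "site_positions": [10, 20], "metal_element": "MG"},
        {"accession": "P10003", "coenzyme_class": "Ascorbic acid",
         "site_positions": [30]},
    ]}
    bundle = Bundle(
        sequences=sequences,
        contacts_by_structure=contacts,
        sifts_rows=sifts_rows,
        ss_rows=ss_rows,
        ecod_rows=ecod_rows,
        conservation_rows=cons_rows,
        truth=truth,
    )
    expected = {
        # interaction ratios per (accession, class, position)
        "ratios": {
            ("P10001", "NAD", 12): (2, 2),
            ("P10001", "NAD", 40): (1, 2),
            ("P10001", "NAD", 55): (2, 2),
            ("P10002", "NAD", 10): (1, 1),
            ("P10002", "NAD", 20): (1, 1),
            ("P10003", "Ascorbic acid", 30): (1, 1),
        },
        # era counts: Ancient sites have G,D,R + G,S -> 4 early, 1 late
        "ancient_early_count": 4,
        "ancient_late_count": 1,
        "postluca_early_count": 1,
        "postluca_late_count": 0,
        # hand-computed Pearson statistic for the 2x2 era x temporality
        # contingency table [[4, 1], [1, 0]]
        "chi2_era_temporality": 0.24,
        "early_exclusive_accessions": ["P10002"],
        "late_exclusive_accessions": [],
        "metal_fraction_ancient": 0.5,   # P10002 of {P10001, P10002}
        "conservation_fraction_ge7": 1.0,
        "conservation_fraction_max_identity": 0.5,
        "fold_diversity": {"NAD": 2, "Ascorbic acid": 1},
        # dropped inputs planted in structure 9aaa
        "n_water": 1, "n_nonstandard": 1, "n_clash_only": 1,
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle, expected
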