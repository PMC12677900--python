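"""Interaction-ratio consensus site calling."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coenzsites.binding_sites import (
    ContactMode,
    call_sites,
    classify_contact_mode,
    compute_interaction_ratio,
)
from coenzsites.ingest import LiftedContact
from coenzsites.manifest import Manifest
from coenzsites.registry import ContactGroup, RAW_LABEL_GROUPS

NON_CLASH_LABELS = sorted(
    l for l, g in RAW_LABEL_GROUPS.items() if g is not ContactGroup.CLASHES
)


def lifted(acc="P1", pos=10, sid="1abc", resname="GLY", atom="N",
           ligand="NAD", labels=("hbond",), metal=False, instance=None,
           environment=None):
    instance = instance or f"{ligand}_1"
    return LiftedContact(
        uniprot_accession=acc, uniprot_position=pos, structure_id=sid,
        residue_name=resname, atom_name=atom, ligand_code=ligand,
        ligand_instance=instance, raw_labels=tuple(labels),
        partner_is_metal=metal, environment=environment or instance,
    )


class TestInteractionRatio:
    @pytest.mark.parametrize("presence,expected", [
        ([True], Fraction(1)),
        ([True, True, False], Fraction(2, 3)),
        ([True, False], Fraction(1, 2)),
        ([False, False], Fraction(0)),
    ])
    def test_exact_rational_values(self, presence, expected):
        assert compute_interaction_ratio(presence) == expected

    def test_empty_vector_is_error(self):
        with pytest.raises(ValueError):
            compute_interaction_ratio([])

    @given(st.lists(st.booleans(), min_size=1, max_size=30))
    def test_ratio_bounds_and_denominator(self, presence):
        r = compute_interaction_ratio(presence)
        assert 0 <= r <= 1
        assert r == Fraction(sum(presence), len(presence))


class TestContactMode:
    @pytest.mark.parametrize("atoms,expected", [
        ({"CA", "O"}, ContactMode.BACKBONE_ONLY),
        ({"N"}, ContactMode.BACKBONE_ONLY),
        ({"CB"}, ContactMode.SIDECHAIN_ONLY),
        ({"N", "CB"}, ContactMode.BOTH),
        ({"OD1", "OD2", "C"}, ContactMode.BOTH),
    ])
    def test_partition(self, atoms, expected):
        assert classify_contact_mode(atoms) is expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            classify_contact_mode(set())


class TestCallSitesExamples:
    def test_single_structure_all_ratios_one(self, registry):
        contacts = [
            lifted(pos=12), lifted(pos=40, resname="ASP", atom="OD1"),
        ]
        (site,) = call_sites(contacts, registry)
        assert site.n_structures == 1
        assert [(r.uniprot_position, r.interaction_ratio)
                for r in site.residues] == [(12, Fraction(1)),
                                            (40, Fraction(1))]

    def test_four_structures_threshold_filters(self, registry):
        contacts = []
        for sid in ("1aaa", "1aab"):
            contacts.append(lifted(pos=12, sid=sid))
        contacts.append(lifted(pos=40, sid="1aaa", resname="ASP", atom="OD1"))
        for sid in ("1aac", "1aad"):  # structures with other residues only
            contacts.append(lifted(pos=7, sid=sid, resname="SER", atom="OG"))
        (site,) = call_sites(contacts, registry)
        assert site.n_structures == 4
        # pos 12 and 7 sit at ratio 2/4 and qualify; pos 40 at 1/4 does not
        assert site.positions == [7, 12]
        assert all(r.interaction_ratio == Fraction(1, 2)
                   for r in site.residues)

    def test_exact_tie_exclusive_mode_drops_half(self, registry):
        contacts = [
            lifted(pos=12, sid="1aaa"),
            lifted(pos=7, sid="1aab", resname="SER", atom="OG"),
        ]
        sites = call_sites(contacts, registry, inclusive=False)
        assert sites == []
        sites = call_sites(contacts, registry, inclusive=True)
        assert len(sites) == 1 and sites[0].positions == [7, 12]

    def test_two_coenzyme_classes_two_sites(self, registry):
        contacts = [
            lifted(pos=12, ligand="NAD"),
            lifted(pos=30, ligand="ATP", resname="THR", atom="OG1"),
        ]
        sites = call_sites(contacts, registry)
        assert {(s.coenzyme_class, tuple(s.positions)) for s in sites} == {
            ("NAD", (12,)), ("ATP", (30,)),
        }

    def test_clash_only_contacts_never_create_presence(self, registry):
        contacts = [
            lifted(pos=12, sid="1aaa"),
            lifted(pos=12, sid="1aab", labels=("vdw_clash",)),
            lifted(pos=12, sid="1aab"),  # real contact in 1aab too
            lifted(pos=40, sid="1aab", labels=("clash", "vdw_clash"),
                   resname="ASP", atom="OD1"),
        ]
        manifest = Manifest()
        (site,) = call_sites(contacts, registry, manifest=manifest)
        assert site.positions == [12]
        assert manifest.sections["contacts"].drops["clash_only"] == 2

    def test_metal_association_via_environment(self, registry):
        contacts = [
            lifted(pos=12),
            lifted(pos=12, ligand="MG", labels=("metal",), metal=True,
                   instance="MG_1", environment="NAD_1"),
            lifted(pos=12, ligand="MG", labels=("metal",), metal=True,
                   instance="MG_2", environment="NAD_1"),
        ]
        (site,) = call_sites(contacts, registry)
        assert site.has_metal
        assert site.metal_ions == {"MG": 2}   # two ion copies, one element
        assert site.metal_elements == {"MG"}

    def test_unregistered_ligand_dropped(self, registry):
        manifest = Manifest()
        sites = call_sites(
            [lifted(ligand="XYZ"), lifted(pos=11)], registry,
            manifest=manifest,
        )
        assert len(sites) == 1
        assert manifest.sections["contacts"].drops["unregistered_ligand"] == 1

    def test_gly_backbone_rule_holds_on_fixture(self, minimal_fixture,
                                                registry):
        bundle, _ = minimal_fixture
        from coenzsites.ingest import lift_to_uniprot

        sites = call_sites(
            lift_to_uniprot(bundle.contact_records(), bundle.sifts_map()),
            registry,
        )
        for site in sites:
            for res in site.residues:
                if res.residue_name == "GLY":
                    assert res.contact_mode is ContactMode.BACKBONE_ONLY


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


def sites_oracle(contacts, registry, threshold=Fraction(1, 2),
                 inclusive=True):
    """Exhaustive per-residue enumeration, written independently.

    Returns {(acc, class): {pos: ratio}} using exact rational comparison.
    """
    from coenzsites.registry import classify_contact_group, is_clash_only

    usable = []
    for c in contacts:
        if c.partner_is_metal:
            continue
        groups = classify_contact_group(c.raw_labels)
        if not groups or is_clash_only(groups):
            continue
        cls = registry.class_for_ligand(c.ligand_code)
        if cls is None or cls.excluded:
            continue
        usable.append((c, cls.class_name))
    result = {}
    for acc in {c.uniprot_accession for c, _ in usable}:
        for cls_name in {cl for c, cl in usable if c.uniprot_accession == acc}:
            pool = [c for c, cl in usable
                    if c.uniprot_accession == acc and cl == cls_name]
            structures = {c.structure_id for c in pool}
            kept = {}
            for pos in {c.uniprot_position for c in pool}:
                n_present = sum(
                    1 for s in structures
                    if any(c.structure_id == s and c.uniprot_position == pos
                           for c in pool)
                )
                ratio = Fraction(n_present, len(structures))
                ok = ratio >= threshold if inclusive else ratio > threshold
                if ok:
                    kept[pos] = ratio
            if kept:
                result[(acc, cls_name)] = kept
    return result


def random_dataset(rng):
    """A random small contact dataset (<=10 proteins, <=5 structures each)."""
    residues = ["GLY", "ALA", "SER", "ASP", "ARG", "HIS", "LEU", "TRP"]
    atoms = {"GLY": ["N", "CA"], "ALA": ["CB", "O"], "SER": ["OG", "N"],
             "ASP": ["OD1", "CB"], "ARG": ["NH1", "C"], "HIS": ["ND1"],
             "LEU": ["CD1", "CA"], "TRP": ["NE1"]}
    ligands = ["NAD", "ATP", "ASC", "SAM", "HEM", "XYZ"]
    contacts = []
    n_proteins = int(rng.integers(1, 11))
    sid_counter = 0
    for p in range(n_proteins):
        acc = f"P{p}"
        n_structs = int(rng.integers(1, 6))
        sids = []
        for _ in range(n_structs):
            sids.append(f"s{sid_counter:03d}")
            sid_counter += 1
        n_residues = int(rng.integers(1, 21))
        positions = rng.choice(200, size=n_residues, replace=False) + 1
        for pos in positions:
            resname = residues[int(rng.integers(len(residues)))]
            ligand = ligands[int(rng.integers(len(ligands)))]
            for sid in sids:
                if rng.random() < 0.55:
                    labels = [NON_CLASH_LABELS[int(
                        rng.integers(len(NON_CLASH_LABELS)))]]
                    if rng.random() < 0.1:
                        labels = ["vdw_clash"]
                    contacts.append(lifted(
                        acc=acc, pos=int(pos), sid=sid, resname=resname,
                        atom=atoms[resname][int(
                            rng.integers(len(atoms[resname])))],
                        ligand=ligand, labels=labels,
                    ))
    return contacts


def as_comparable(sites):
    return {
        (s.uniprot_accession, s.coenzyme_class): {
            r.uniprot_position: r.interaction_ratio for r in s.residues
        }
        for s in sites
    }


class TestOracleEquivalence:
    def test_random_small_datasets_match_enumeration(self, registry):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            contacts = random_dataset(rng)
            for inclusive in (True, False):
                got = as_comparable(call_sites(
                    contacts, registry, inclusive=inclusive
                ))
                want = sites_oracle(contacts, registry, inclusive=inclusive)
                assert got == want

    def test_threshold_monotonicity(self, registry):
        rng = np.random.default_rng(7)
        contacts = random_dataset(rng)
        thresholds = [Fraction(n, 10) for n in range(1, 11)]
        prev = None
        for th in thresholds:
            cur = as_comparable(call_sites(contacts, registry, threshold=th))
            if prev is not None:
                for key, res in cur.items():
                    assert set(res) <= set(prev.get(key, res))
            prev = cur
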