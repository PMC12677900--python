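"""Contact reading, UniProt lifting, and identity clustering."""

import json
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coenzsites.ingest import (
    cluster_sequences,
    lift_to_uniprot,
    read_contacts,
    read_residue_map_tsv,
    read_sifts_tsv,
    sequence_identity,
)
from coenzsites.manifest import Manifest


def _contact(resnum=10, resname="GLY", atom="N", ligand="NAD", labels=None,
             chain="A", icode=""):
    return {
        "chain": chain, "resnum": resnum, "icode": icode, "resname": resname,
        "atom": atom, "ligand": ligand, "ligand_instance": f"{ligand}_1",
        "labels": labels or ["hbond"],
    }


def _write_contacts(tmp_path, entries, structure_id="1abc"):
    path = tmp_path / f"{structure_id}.json"
    path.write_text(json.dumps({
        "schema": 1, "structure_id": structure_id, "contacts": entries,
    }))
    return path


class TestReadContacts:
    def test_water_contacts_dropped(self, tmp_path):
        path = _write_contacts(tmp_path, [
            _contact(resnum=1), _contact(resnum=2, resname="SER", atom="OG"),
            _contact(resnum=3, resname="HOH", atom="O"),
        ])
        manifest = Manifest()
        records = read_contacts(path, manifest)
        assert len(records) == 2
        assert manifest.sections["contacts"].drops["water"] == 1

    def test_nonstandard_residue_excluded_and_counted(self, tmp_path):
        path = _write_contacts(tmp_path, [
            _contact(), _contact(resnum=5, resname="MSE", atom="SE"),
        ])
        manifest = Manifest()
        records = read_contacts(path, manifest)
        assert [r.residue_name for r in records] == ["GLY"]
        assert manifest.sections["contacts"].drops["nonstandard_residue"] == 1

    def test_metal_partner_derived_from_ligand_code(self, tmp_path):
        path = _write_contacts(tmp_path, [
            _contact(ligand="MG", labels=["metal"]), _contact(),
        ])
        records = read_contacts(path)
        flags = {r.ligand_code: r.partner_is_metal for r in records}
        assert flags == {"MG": True, "NAD": False}

    def test_no_valid_records_is_error(self, tmp_path):
        path = _write_contacts(tmp_path, [_contact(resname="HOH")])
        with pytest.raises(ValueError, match="no valid contact"):
            read_contacts(path)

    def test_missing_schema_is_error(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text(json.dumps({"structure_id": "1abc", "contacts": []}))
        with pytest.raises(ValueError, match="schema"):
            read_contacts(path)

    def test_malformed_record_skipped_and_counted(self, tmp_path):
        path = _write_contacts(tmp_path, [
            _contact(), {"chain": "A", "resnum": "not-a-number"},
        ])
        manifest = Manifest()
        records = read_contacts(path, manifest)
        assert len(records) == 1
        assert manifest.sections["contacts"].drops["malformed"] == 1

    def test_insertion_code_in_residue_key(self, tmp_path):
        path = _write_contacts(tmp_path, [_contact(resnum=100, icode="A")])
        (rec,) = read_contacts(path)
        assert rec.residue_key == "100A"


class TestSiftsMaps:
    def test_range_dialect_expansion(self, tmp_path):
        p = tmp_path / "sifts.tsv"
        p.write_text(
            "PDB\tCHAIN\tSP_PRIMARY\tRES_BEG\tRES_END\tPDB_BEG\tPDB_END\t"
            "SP_BEG\tSP_END\n"
            "1abc\tA\tP12345\t1\t50\t101\t150\t1\t50\n"
        )
        smap = read_sifts_tsv(p)
        assert len(smap) == 50
        assert smap.get("1abc", "A", "101") == ("P12345", 1)
        assert smap.get("1abc", "A", "150") == ("P12345", 50)

    def test_per_residue_dialect_with_icode(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text(
            "PDB\tCHAIN\tPDB_RES\tSP_PRIMARY\tSP_RES\n"
            "1abc\tA\t100A\tP12345\t42\n"
        )
        smap = read_residue_map_tsv(p)
        assert smap.get("1abc", "A", "100A") == ("P12345", 42)

    def test_chimeric_residue_dropped_as_ambiguous(self):
        from coenzsites.ingest import SiftsResidueMap

        smap = SiftsResidueMap()
        smap.add("1abc", "A", "10", "P1", 10)
        smap.add("1abc", "A", "10", "P2", 99)
        smap.add("1abc", "A", "10", "P1", 10)  # must stay dropped
        assert smap.get("1abc", "A", "10") is None
        assert smap.n_ambiguous_dropped == 1


class TestLifting:
    def _records(self, tmp_path, entries, structure_id="1abc"):
        return read_contacts(
            _write_contacts(tmp_path, entries, structure_id)
        )

    def test_unmappable_contacts_dropped_and_counted(self, tmp_path):
        from coenzsites.ingest import SiftsResidueMap

        recs = self._records(tmp_path, [
            _contact(resnum=n) for n in (1, 2, 3, 4, 99)
        ])
        smap = SiftsResidueMap()
        for n in (1, 2, 3, 4):
            smap.add("1abc", "A", str(n), "P1", n)
        manifest = Manifest()
        lifted = lift_to_uniprot(recs, smap, manifest)
        assert len(lifted) == 4
        assert manifest.sections["contacts"].drops["unmapped"] == 1

    def test_different_author_numbering_same_uniprot_key(self, tmp_path):
        from coenzsites.ingest import SiftsResidueMap

        recs = self._records(tmp_path, [_contact(resnum=12)], "1abc")
        recs += self._records(tmp_path, [_contact(resnum=112)], "2xyz")
        smap = SiftsResidueMap()
        smap.add("1abc", "A", "12", "P1", 12)
        smap.add("2xyz", "A", "112", "P1", 12)
        lifted = lift_to_uniprot(recs, smap)
        keys = {(r.uniprot_accession, r.uniprot_position) for r in lifted}
        assert keys == {("P1", 12)}

    def test_empty_map_is_error(self, tmp_path):
        from coenzsites.ingest import SiftsResidueMap

        recs = self._records(tmp_path, [_contact()])
        with pytest.raises(ValueError, match="empty"):
            lift_to_uniprot(recs, SiftsResidueMap())


# ---------------------------------------------------------------------------
# identity + clustering, with brute-force oracle


def identity_oracle(a: str, b: str) -> Fraction:
    """Independent pure-python recomputation of the ungapped identity."""
    if len(a) < len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0
    for shift in range(-(lb - 1), la):
        m = sum(
            1 for i in range(lb)
            if 0 <= shift + i < la and a[shift + i] == b[i]
        )
        best = max(best, m)
    return Fraction(best, lb)


def cluster_oracle(seqs: dict, threshold: float) -> dict:
    """All-pairs brute-force clustering with the same greedy rule."""
    th = Fraction(threshold).limit_denominator(10**6)
    items = sorted(seqs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[dict] = []
    for acc, seq in items:
        if len(seq) < 10:
            clusters.append({"rep": acc, "rep_seq": None, "members": [acc]})
            continue
        for c in clusters:
            if c["rep_seq"] is not None and (
                identity_oracle(seq, c["rep_seq"]) >= th
            ):
                c["members"].append(acc)
                break
        else:
            clusters.append({"rep": acc, "rep_seq": seq, "members": [acc]})
    return {c["rep"]: frozenset(c["members"]) for c in clusters}


def _mutate(rng, seq: str, n_subs: int) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        chars[pos] = alphabet[int(rng.integers(20))]
    return "".join(chars)


def make_families(rng, n_families=10, copies=5, length=80, max_subs=4):
    seqs = {}
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for f in range(n_families):
        base = "".join(
            alphabet[int(i)] for i in rng.integers(20, size=length)
        )
        for c in range(copies):
            n_subs = int(rng.integers(0, max_subs + 1)) if c else 0
            seqs[f"F{f:02d}C{c}"] = _mutate(rng, base, n_subs)
    return seqs


class TestIdentity:
    @given(st.text(alphabet="ACDG", min_size=1, max_size=30),
           st.text(alphabet="ACDG", min_size=1, max_size=30))
    def test_matches_oracle_and_symmetric(self, a, b):
        assert sequence_identity(a, b) == identity_oracle(a, b)
        assert sequence_identity(a, b) == sequence_identity(b, a)

    @given(st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=50))
    def test_self_identity_is_one(self, a):
        assert sequence_identity(a, a) == 1


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        clusters = cluster_sequences(
            {"A1": "MKTLLVVAAA", "A2": "MKTLLVVAAA"}, threshold=0.9
        )
        assert len(clusters) == 1
        assert clusters[0].members == {"A1", "A2"}

    def test_half_identity_gives_singletons_at_90pct(self):
        a = "AAAAAAAAAACCCCCCCCCC"
        b = "AAAAAAAAAAGGGGGGGGGG"
        assert sequence_identity(a, b) == Fraction(1, 2)
        clusters = cluster_sequences({"A": a, "B": b}, threshold=0.9)
        assert len(clusters) == 2

    def test_mutated_families_recovered(self):
        rng = np.random.default_rng(11)
        seqs = make_families(rng)
        clusters = cluster_sequences(seqs, threshold=0.9)
        assert len(clusters) == 10
        got = {c.representative: c.members for c in clusters}
        assert got == cluster_oracle(seqs, 0.9)
        # every cluster is one family
        for members in got.values():
            assert len({m[:3] for m in members}) == 1

    def test_threshold_one_groups_only_exact_duplicates(self):
        rng = np.random.default_rng(12)
        seqs = make_families(rng, n_families=5, copies=3, max_subs=2)
        seqs["DUP0"] = seqs["F00C0"]
        clusters = cluster_sequences(seqs, threshold=1.0)
        for c in clusters:
            assert len({seqs[m] for m in c.members}) == 1
        assert any(c.members >= {"F00C0", "DUP0"} for c in clusters)

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(13)
        seqs = make_families(rng)
        counts = [
            len(cluster_sequences(seqs, threshold=t))
            for t in (0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert counts == sorted(counts)

    def test_short_sequence_becomes_singleton(self, caplog):
        clusters = cluster_sequences(
            {"S": "MKT", "L": "MKTLLVVAAAGGG"}, threshold=0.9
        )
        assert {frozenset(c.members) for c in clusters} == {
            frozenset({"S"}), frozenset({"L"}),
        }
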