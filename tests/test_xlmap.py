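"""Crosslink parsing, assignment enumeration, clash testing, and satisfaction."""

import numpy as np
import pytest

from sarmdyn.errors import InputError
from sarmdyn.structure_io import Atom, Chain, Residue, StructureModel
from sarmdyn.synthetic import SyntheticConfig, simulate_crosslinks
from sarmdyn.xlmap import (
    CrosslinkRecord,
    XlAssignment,
    XlConfig,
    best_assignment,
    condition_specific,
    enumerate_assignments,
    line_clash,
    parse_crosslinks,
    summarize,
)


def ca_structure(chains: dict[str, dict[int, tuple]], names=None) -> StructureModel:
    """Build a CA-only structure from {chain: {res_num: (x, y, z)}}."""
    model = StructureModel(id="toy")
    for cid, residues in chains.items():
        chain = Chain(chain_id=cid)
        for num in sorted(residues):
            chain.residues.append(
                Residue(
                    res_num=num,
                    insertion_code="",
                    res_name=(names or {}).get((cid, num), "LYS"),
                    atoms=[
                        Atom(name="CA", element="C",
                             coords=np.array(residues[num], dtype=float))
                    ],
                )
            )
        model.chains.append(chain)
    return model


class TestParse:
    def test_three_row_echo(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text(
            "xl_id,res_a,res_b,condition,n_csms\n"
            "x1,10,20,NAD,2\nx2,5,30,NAD,1\nx3,8,40,NMN,3\n"
        )
        records = parse_crosslinks(p)
        assert len(records) == 3
        assert records[0].pair == (10, 20) and records[0].n_csms == 2

    def test_swapped_duplicates_merge(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text("res_a,res_b,condition\n10,20,NAD\n20,10,NAD\n")
        records = parse_crosslinks(p)
        assert len(records) == 1
        assert records[0].pair == (10, 20) and records[0].n_csms == 2

    def test_noninteger_residue_names_line(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text("res_a,res_b\n10,20\nK12a,30\n")
        with pytest.raises(InputError, match="line 3"):
            parse_crosslinks(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text("res_a,condition\n10,NAD\n")
        with pytest.raises(InputError, match="res_b"):
            parse_crosslinks(p)


class TestEnumerate:
    def test_homodimer_three_canonical_assignments(self):
        model = ca_structure(
            {
                "A": {10: (0, 0, 0), 20: (10, 0, 0)},
                "B": {10: (0, 40, 0), 20: (10, 40, 0)},
            }
        )
        rec = CrosslinkRecord("x", 10, 20)
        pairs = {(a.chain_a, a.chain_b) for a in enumerate_assignments(rec, model)}
        assert pairs == {("A", "A"), ("A", "B"), ("B", "B")}

    def test_hand_geometry_satisfied(self):
        model = ca_structure({"A": {10: (0, 0, 0), 20: (0, 0, 25)}})
        (a,) = enumerate_assignments(CrosslinkRecord("x", 10, 20), model)
        assert a.distance_ca_ca == pytest.approx(25.0)
        assert a.satisfied and a.topology == "intra"

    def test_beyond_cutoff_violated(self):
        model = ca_structure({"A": {10: (0, 0, 0), 20: (0, 0, 40)}})
        (a,) = enumerate_assignments(CrosslinkRecord("x", 10, 20), model)
        assert not a.satisfied

    def test_heterologous_pair_keeps_shorter_orientation(self):
        # res10(A)-res20(B) is 10 Å; res10(B)-res20(A) is ~41 Å
        model = ca_structure(
            {
                "A": {10: (0, 0, 0), 20: (40, 10, 0)},
                "B": {10: (40, 0, 0), 20: (10, 0, 0)},
            }
        )
        inter = [
            a for a in enumerate_assignments(CrosslinkRecord("x", 10, 20), model)
            if a.topology == "inter"
        ]
        assert len(inter) == 1
        assert inter[0].distance_ca_ca == pytest.approx(10.0)

    def test_unmappable_record_returns_empty(self, ring):
        assert enumerate_assignments(CrosslinkRecord("x", 900, 901), ring) == []

    def test_distance_symmetric_in_residue_order(self, ring):
        a1 = enumerate_assignments(CrosslinkRecord("x", 4, 28), ring)
        a2 = enumerate_assignments(CrosslinkRecord("x", 28, 4), ring)
        d1 = sorted(round(a.distance_ca_ca, 9) for a in a1)
        d2 = sorted(round(a.distance_ca_ca, 9) for a in a2)
        assert d1 == d2


class TestBest:
    def _mk(self, chain_a, chain_b, d):
        topo = "intra" if chain_a == chain_b else "inter"
        return XlAssignment("x", chain_a, chain_b, d, d <= 30, topo)

    def test_minimum_distance_wins(self):
        best = best_assignment([self._mk("A", "A", 28.0), self._mk("A", "B", 12.0)])
        assert best.topology == "inter" and best.is_best

    def test_tie_prefers_intra(self):
        best = best_assignment([self._mk("A", "B", 15.0), self._mk("A", "A", 15.0)])
        assert best.topology == "intra"

    def test_single_assignment_identity(self):
        a = self._mk("A", "A", 5.0)
        assert best_assignment([a]) is a

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            best_assignment([])

    def test_agrees_with_bruteforce_on_ring(self, ring):
        cfg = XlConfig()
        for pair in [(1, 8), (4, 24), (8, 40), (1, 40)]:
            rec = CrosslinkRecord("x", *pair)
            best = best_assignment(enumerate_assignments(rec, ring, cfg))
            # brute force over every chain pair and orientation
            d_min = np.inf
            for ca in ring.chains:
                for cb in ring.chains:
                    ra = ca.residue(rec.res_a)
                    rb = cb.residue(rec.res_b)
                    if ra is None or rb is None:
                        continue
                    d = np.linalg.norm(ra.atom("CA").coords - rb.atom("CA").coords)
                    if d > 0:
                        d_min = min(d_min, d)
            assert best.distance_ca_ca == pytest.approx(d_min, abs=1e-9)


def point_segment_distance(p, a, b, t0, t1):
    """Exact distance from point p to the sub-segment a..b restricted to [t0, t1]."""
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), t0, t1)
    return float(np.linalg.norm(a + t * ab - p))


class TestLineClash:
    def test_empty_region_no_clash(self):
        model = ca_structure({"A": {1: (100, 100, 100)}})
        assert not line_clash(model, (0, 0, 0), (0, 0, 20), set())

    def test_midpoint_atom_within_probe(self):
        model = ca_structure({"A": {1: (1.0, 0, 10)}})  # 1 Å off-axis at midpoint
        cfg = XlConfig(clash_probe_radius=2.0)
        assert line_clash(model, (0, 0, 0), (0, 0, 20), set(), cfg)

    def test_excluded_residue_ignored(self):
        model = ca_structure({"A": {1: (1.0, 0, 10)}})
        assert not line_clash(model, (0, 0, 0), (0, 0, 20), {("A", 1)}, XlConfig())

    def test_neighbor_window_expands_exclusion(self):
        model = ca_structure({"A": {2: (1.0, 0, 10)}})
        cfg = XlConfig(neighbor_window=1)
        assert not line_clash(model, (0, 0, 0), (0, 0, 20), {("A", 1)}, cfg)

    def test_agrees_with_exact_point_to_segment_oracle(self, rng):
        cfg = XlConfig(clash_step=0.25)
        pa, pb = np.array([0.0, 0, 0]), np.array([0.0, 0, 30])
        for _ in range(50):
            atom = rng.uniform(-5, 35, size=3)[[1, 2, 0]]  # scattered points
            model = ca_structure({"A": {1: tuple(atom)}})
            exact = point_segment_distance(
                atom, pa, pb, cfg.endpoint_margin, 1 - cfg.endpoint_margin
            )
            got = line_clash(model, pa, pb, set(), cfg)
            if exact < cfg.clash_probe_radius - 0.15:
                assert got
            elif exact > cfg.clash_probe_radius + 0.15:
                assert not got
            # within the sampling tolerance band either verdict is acceptable


class TestSummarize:
    def test_truth_labels_recovered(self, ring):
        cfg = SyntheticConfig(seed=11, n_true=8, n_decoy=2)
        records, labels = simulate_crosslinks(ring, cfg)
        summary, _, bests = summarize(records, ring)
        assert summary.satisfaction_fraction == pytest.approx(80.0)
        for b in bests:
            assert (b.satisfied and not b.clash) == labels[b.xl_id]

    def test_all_decoys_zero_fraction(self, ring):
        cfg = SyntheticConfig(seed=5, n_true=0, n_decoy=5)
        records, _ = simulate_crosslinks(ring, cfg)
        summary, _, _ = summarize(records, ring)
        assert summary.satisfaction_fraction == pytest.approx(0.0)

    def test_all_true_full_fraction(self, ring):
        cfg = SyntheticConfig(seed=5, n_true=6, n_decoy=0)
        records, _ = simulate_crosslinks(ring, cfg)
        summary, _, _ = summarize(records, ring)
        assert summary.satisfaction_fraction == pytest.approx(100.0)

    def test_unmappable_only_flags_undefined(self, ring):
        records = [CrosslinkRecord("x", 500, 600)]
        summary, _, _ = summarize(records, ring)
        assert summary.n_mapped == 0
        assert summary.satisfaction_fraction is None
        assert summary.to_dict()["fraction_undefined"]

    def test_fraction_monotone_in_cutoff(self, ring):
        cfg = SyntheticConfig(seed=13, n_true=8, n_decoy=4)
        records, _ = simulate_crosslinks(ring, cfg)
        fractions = []
        for cutoff in (10, 20, 25, 30, 35, 45, 60, 80):
            summary, _, _ = summarize(records, ring, XlConfig(cutoff_ca_ca=cutoff))
            fractions.append(summary.satisfaction_fraction)
        assert fractions == sorted(fractions)

    def test_region_breakdown_uses_table(self):
        model = ca_structure(
            {"A": {100: (0, 0, 0), 500: (0, 0, 10), 600: (0, 0, 50)}}
        )
        cfg = XlConfig(regions={"ARM": (60, 402), "SAM": (403, 549), "TIR": (561, 701)})
        records = [CrosslinkRecord("x1", 100, 500), CrosslinkRecord("x2", 500, 600)]
        summary, _, _ = summarize(records, model, cfg)
        assert summary.by_region["ARM-SAM"]["mapped"] == 1
        assert summary.by_region["SAM-TIR"]["mapped"] == 1


class TestConditionSpecific:
    def _recs(self, pairs, cond="NMN"):
        return [CrosslinkRecord(f"x{i}", a, b, cond) for i, (a, b) in enumerate(pairs)]

    def test_identical_lists_empty(self):
        a = self._recs([(1, 5), (2, 6)])
        assert condition_specific(a, self._recs([(1, 5), (2, 6)], "NAD")) == []

    def test_disjoint_lists_all_of_a(self):
        a = self._recs([(1, 5), (2, 6)])
        assert condition_specific(a, self._recs([(3, 7)], "NAD")) == a

    def test_partial_overlap(self):
        a = self._recs([(1, 5), (2, 6)])
        out = condition_specific(a, self._recs([(2, 6)], "NAD"))
        assert [r.pair for r in out] == [(1, 5)]
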