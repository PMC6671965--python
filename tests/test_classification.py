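"""Class-graph reduction: refinement, canonical keys, archetype matching."""

import itertools

import numpy as np
import pytest

import signedbalance as sb
from signedbalance.classification import InconsistentPartitionError

from conftest import random_sign_matrix


# ---------------------------------------------------------------------------
# brute-force oracle: coarsest sign-uniform equitable partition by
# exhaustive search over the set-partition lattice (feasible for n <= 5)


def set_partitions(items):
    if not items:
        yield []
        return
    head = items[0]
    for part in set_partitions(items[1:]):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def is_sign_uniform(s, blocks):
    for a in blocks:
        for b in blocks:
            vals = [s[i, j] for i in a for j in b if i != j]
            if vals and any(v != vals[0] for v in vals):
                return False
    return True


def is_equitable(s, blocks):
    pos = s == 1
    for a in blocks:
        for b in blocks:
            outs = {sum(pos[i, j] for j in b if j != i) for i in a}
            ins = {sum(pos[j, i] for j in b if j != i) for i in a}
            if len(outs) > 1 or len(ins) > 1:
                return False
    return True


def coarsest_valid_partitions(s: np.ndarray):
    """All sign-uniform equitable partitions with the fewest blocks."""
    n = s.shape[0]
    best: list[frozenset] = []
    best_c = n + 1
    for part in set_partitions(list(range(n))):
        if len(part) > best_c:
            continue
        if is_sign_uniform(s, part) and is_equitable(s, part):
            as_sets = frozenset(frozenset(b) for b in part)
            if len(part) < best_c:
                best, best_c = [as_sets], len(part)
            elif as_sets not in best:
                best.append(as_sets)
    return best


class TestRefineClasses:
    def test_all_friendly_is_one_class(self):
        s = sb.make_template(sb.TemplateSpec("HB", (6, 0)))
        assert sb.refine_classes(s).sizes == (6,)

    def test_all_hostile_is_one_class(self):
        s = sb.SignMatrix(-(np.ones((5, 5)) - np.eye(5)))
        assert sb.refine_classes(s).sizes == (5,)

    def test_equal_hb_cliques_are_separated(self):
        # every node has identical degree counts; the positive components
        # must seed the split
        s = sb.make_template(sb.TemplateSpec("HB", (4, 4)))
        p = sb.refine_classes(s)
        assert p.sizes == (4, 4)
        assert p.as_sets() == frozenset(
            {frozenset(range(4)), frozenset(range(4, 8))})

    @pytest.mark.parametrize(
        "kind,sizes",
        [("CII", (5, 2)), ("CIII", (3, 3, 1)), ("CIV", (4, 3, 2, 1))],
    )
    def test_templates_recover_their_blocks(self, kind, sizes):
        spec = sb.TemplateSpec(kind, sizes)
        s = sb.make_template(spec)
        p = sb.refine_classes(s)
        assert sorted(p.sizes, reverse=True) == sorted(sizes, reverse=True)
        g = sb.class_graph(s, p)
        got = sb.identify_template(g)
        assert got is not None and got.kind == kind

    def test_idempotent_on_quotient_consistent_states(self, rng):
        for _ in range(10):
            s = random_sign_matrix(6, rng)
            p1 = sb.refine_classes(s)
            assert sb.refine_classes(s).as_sets() == p1.as_sets()

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_bruteforce_partition_oracle(self, n, rng):
        cases = [random_sign_matrix(n, rng) for _ in range(25)]
        cases.append(sb.SignMatrix(np.ones((n, n)) - np.eye(n)))
        cases.append(sb.SignMatrix(-(np.ones((n, n)) - np.eye(n))))
        if n == 4:
            cases.append(sb.make_template(sb.TemplateSpec("HB", (2, 2))))
        for s in cases:
            ours = sb.refine_classes(s)
            valid = coarsest_valid_partitions(s.s)
            assert ours.as_sets() in valid, s.s

    def test_permutation_invariance_of_canonical_key(self, rng):
        s = sb.make_template(sb.TemplateSpec("CIV", (4, 3, 2, 1)))
        base = sb.canonical_key(sb.class_graph(s, sb.refine_classes(s)))
        for _ in range(8):
            sp = s.permuted(rng.permutation(s.n))
            key = sb.canonical_key(sb.class_graph(sp, sb.refine_classes(sp)))
            assert key == base


class TestClassGraph:
    def test_hb_block_signs(self):
        s = sb.make_template(sb.TemplateSpec("HB", (4, 3)))
        g = sb.class_graph(s, sb.refine_classes(s))
        assert g.sizes == (4, 3)
        assert np.array_equal(g.rel, [[1, -1], [-1, 1]])

    def test_cii_block_signs(self):
        s = sb.make_template(sb.TemplateSpec("CII", (5, 2)))
        g = sb.class_graph(s, sb.refine_classes(s))
        assert g.sizes == (5, 2)
        assert np.array_equal(g.rel, [[1, -1], [1, -1]])

    def test_single_class_all_friendly(self):
        s = sb.make_template(sb.TemplateSpec("HB", (4, 0)))
        g = sb.class_graph(s, sb.refine_classes(s))
        assert g.sizes == (4,) and g.rel[0, 0] == 1

    def test_inconsistent_partition_rejected(self):
        s = sb.make_template(sb.TemplateSpec("CIII", (3, 3, 1)))
        bad = sb.Partition((tuple(range(7)),))
        with pytest.raises(InconsistentPartitionError):
            sb.class_graph(s, bad)

    def test_dot_and_json_exports(self, tmp_path):
        s = sb.make_template(sb.TemplateSpec("CIII", (3, 3, 1)))
        g = sb.class_graph(s, sb.refine_classes(s))
        dot = g.to_dot()
        assert "digraph" in dot and "dashed" in dot and "solid" in dot
        assert '"sizes"' in g.to_json()
        g.write_dot(tmp_path / "g.dot")
        assert (tmp_path / "g.dot").exists()


class TestCanonicalKey:
    def test_relabelled_copies_share_keys(self, rng):
        s = sb.make_template(sb.TemplateSpec("CIII", (3, 3, 1)))
        g = sb.class_graph(s, sb.refine_classes(s))
        sp = s.permuted(rng.permutation(7))
        gp = sb.class_graph(sp, sb.refine_classes(sp))
        assert sb.canonical_key(g) == sb.canonical_key(gp)

    def test_sizes_toggle(self):
        g1 = sb.class_graph(*_template_graph("CIV", (4, 3, 2, 1)))
        g2 = sb.class_graph(*_template_graph("CIV", (3, 4, 2, 1)))
        assert sb.canonical_key(g1, with_sizes=True) != sb.canonical_key(
            g2, with_sizes=True)
        assert sb.canonical_key(g1, with_sizes=False) == sb.canonical_key(
            g2, with_sizes=False)

    def test_distinct_archetypes_get_distinct_keys(self):
        g_hb = sb.class_graph(*_template_graph("HB", (4, 3)))
        g_cii = sb.class_graph(*_template_graph("CII", (4, 3)))
        assert sb.canonical_key(g_hb) != sb.canonical_key(g_cii)

    def test_civ_automorphism_collapses_equivalent_labelings(self):
        g1 = sb.class_graph(*_template_graph("CIV", (4, 3, 2, 1)))
        g2 = sb.class_graph(*_template_graph("CIV", (3, 4, 1, 2)))
        assert sb.canonical_key(g1) == sb.canonical_key(g2)


def _template_graph(kind, sizes):
    s = sb.make_template(sb.TemplateSpec(kind, sizes))
    return s, sb.refine_classes(s)


class TestIdentifyTemplate:
    def test_symmetric_two_clique_graph_is_hb(self):
        g = sb.class_graph(*_template_graph("HB", (5, 2)))
        got = sb.identify_template(g)
        assert got.kind == "HB" and got.sizes == (5, 2)

    def test_civ_round_trip(self):
        g = sb.class_graph(*_template_graph("CIV", (4, 3, 2, 1)))
        got = sb.identify_template(g)
        assert got.kind == "CIV" and got.sizes == (4, 3, 2, 1)

    def test_non_archetype_graph_is_other(self):
        # three mutually friendly cliques: no archetype has all-+ blocks
        rel = np.ones((3, 3), dtype=int)
        g = sb.ClassGraph(sizes=(2, 2, 2), rel=rel)
        assert sb.identify_template(g) is None

    def test_role_order_is_sign_determined_not_size_determined(self):
        # class 3 of CIII is recognised by its pattern even when largest
        g = sb.class_graph(*_template_graph("CIII", (3, 2, 4)))
        got = sb.identify_template(g)
        assert got.kind == "CIII" and got.sizes == (3, 2, 4)
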