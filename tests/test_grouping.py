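"""The CVCM-driven similar-class grouping algorithm."""

import logging

import numpy as np
import pytest

from tsidl.confmat import ConfusionMatrix
from tsidl.grouping import (
    GroupingParams,
    SDList,
    SGMap,
    assign_group,
    find_similar_groups,
)


def brute_force_groups(cvcm, package_of, tp_threshold=48, fn_threshold=1):
    """Independent naive re-implementation: red scan, row-wise yellow scan,
    per-package union, singleton dissolution, lexicographic ordering."""
    labels = list(cvcm.labels)
    red = [l for i, l in enumerate(labels) if cvcm.counts[i][i] <= tp_threshold]
    per_pkg: dict[str, set] = {}
    for l in red:
        i = labels.index(l)
        members = {l}
        for j, o in enumerate(labels):
            if j != i and cvcm.counts[i][j] >= fn_threshold and package_of[o] == package_of[l]:
                members.add(o)
        per_pkg.setdefault(package_of[l], set()).update(members)
    groups = []
    for pkg in sorted(per_pkg):
        if len(per_pkg[pkg]) >= 2:
            groups.append((pkg, frozenset(per_pkg[pkg])))
    grouped = set().union(*(m for _, m in groups)) if groups else set()
    return groups, frozenset(set(labels) - grouped)


def _cm(counts, labels=None):
    counts = np.asarray(counts)
    labels = labels or tuple(chr(65 + k) for k in range(len(counts)))
    return ConfusionMatrix(tuple(labels), counts)


class TestFindSimilarGroups:
    def test_default_thresholds(self):
        p = GroupingParams()
        assert p.tp_threshold == 48 and p.fn_threshold == 1 and p.support == 50

    def test_perfect_cvcm_yields_single_residual(self):
        cm = _cm(50 * np.eye(4, dtype=int))
        sg = find_similar_groups(cm, {l: "amp" for l in cm.labels})
        assert sg.n_groups == 0
        assert sg.residual == frozenset(cm.labels)

    def test_worked_three_class_trace(self):
        # A: 47 TP with 3 misses into B; B and C clean
        cm = _cm([[47, 3, 0], [0, 50, 0], [0, 1, 49]])
        sg = find_similar_groups(cm, {"A": "amp", "B": "amp", "C": "amp"})
        assert sg.n_groups == 1
        assert sg.groups[0].members == frozenset({"A", "B"})
        assert sg.residual == frozenset({"C"})

    def test_cross_package_partner_excluded_and_singleton_dissolved(self, caplog):
        # red A (package amp) misses only into D (package bot)
        cm = _cm([[46, 0, 0, 4], [0, 50, 0, 0], [0, 0, 50, 0], [0, 0, 0, 50]])
        pkg = {"A": "amp", "B": "amp", "C": "bot", "D": "bot"}
        with caplog.at_level(logging.WARNING, logger="tsidl.grouping"):
            sg = find_similar_groups(cm, pkg)
        assert sg.n_groups == 0
        assert sg.residual == frozenset("ABCD")
        text = caplog.text
        assert "cross-package" in text and "dissolved" in text

    def test_two_red_classes_same_package_share_one_sd_list(self):
        cm = _cm(
            [[40, 10, 0, 0], [0, 40, 10, 0], [0, 0, 50, 0], [0, 0, 0, 50]]
        )
        pkg = {l: "ccb" for l in "ABCD"}
        sg = find_similar_groups(cm, pkg)
        assert sg.n_groups == 1
        assert sg.groups[0].members == frozenset({"A", "B", "C"})

    def test_matches_brute_force_on_random_cvcms(self):
        rng = np.random.default_rng(21)
        packages = ["amp", "bot", "ccb"]
        for _ in range(200):
            r = int(rng.integers(2, 11))
            labels = tuple(f"d{k}" for k in range(r))
            counts = np.zeros((r, r), int)
            for i in range(r):
                # row sums to 50 with mass concentrated on the diagonal
                off = rng.integers(0, 15)
                counts[i, i] = 50 - off
                for _ in range(int(off)):
                    counts[i, int(rng.integers(0, r))] += 1
                counts[i, i] = max(0, 50 - (counts[i].sum() - counts[i, i]))
            cm = ConfusionMatrix(labels, counts)
            pkg = {l: packages[int(rng.integers(0, 3))] for l in labels}
            sg = find_similar_groups(cm, pkg)
            want_groups, want_res = brute_force_groups(cm, pkg)
            got = [(g.package_class, g.members) for g in sg.groups]
            assert got == want_groups
            assert sg.residual == want_res

    def test_red_set_monotone_in_tp_threshold(self):
        rng = np.random.default_rng(31)
        labels = tuple(f"d{k}" for k in range(6))
        counts = rng.integers(0, 20, (6, 6))
        np.fill_diagonal(counts, rng.integers(30, 51, 6))
        cm = ConfusionMatrix(labels, counts)
        pkg = {l: "amp" for l in labels}
        reds = []
        for thr in (30, 40, 48):
            sg = find_similar_groups(cm, pkg, GroupingParams(tp_threshold=thr))
            reds.append(set(sg.provenance["red"]))
        assert reds[0] <= reds[1] <= reds[2]

    def test_relative_mode_scales_threshold_to_support(self):
        # support 20 per class; 0.96 * 20 = 19.2 -> cut 19
        cm = _cm([[19, 1, 0], [0, 20, 0], [1, 0, 19]])
        pkg = {l: "amp" for l in "ABC"}
        sg = find_similar_groups(cm, pkg, GroupingParams(mode="relative"))
        assert set(sg.provenance["red"]) == {"A", "C"}

    def test_deterministic_including_order(self):
        rng = np.random.default_rng(77)
        counts = rng.integers(0, 10, (5, 5))
        np.fill_diagonal(counts, 40)
        cm = ConfusionMatrix(tuple("ABCDE"), counts)
        pkg = dict(zip("ABCDE", ["bot", "bot", "amp", "amp", "ccb"]))
        a = find_similar_groups(cm, pkg)
        b = find_similar_groups(cm, pkg)
        assert a.to_json() == b.to_json()
        # groups ordered lexicographically by package class
        pkgs = [g.package_class for g in a.groups]
        assert pkgs == sorted(pkgs)

    def test_partition_property(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            r = int(rng.integers(2, 9))
            labels = tuple(f"d{k}" for k in range(r))
            counts = rng.integers(0, 25, (r, r))
            np.fill_diagonal(counts, rng.integers(20, 51, r))
            cm = ConfusionMatrix(labels, counts)
            pkg = {l: f"p{int(rng.integers(0, 2))}" for l in labels}
            sg = find_similar_groups(cm, pkg)
            seen = list(sg.residual) + [m for g in sg.groups for m in g.members]
            assert sorted(seen) == sorted(labels)

    def test_errors(self):
        cm = _cm([[40, 10], [0, 50]])
        with pytest.raises(KeyError, match="'B'"):
            find_similar_groups(cm, {"A": "amp"})
        with pytest.raises(ValueError):
            GroupingParams(tp_threshold=-1)
        with pytest.raises(ValueError):
            GroupingParams(fn_threshold=0)


class TestSGMap:
    def _map(self):
        return SGMap(
            groups=(SDList("amp", {"a1", "a2"}), SDList("bot", {"b1", "b2", "b3"})),
            residual=frozenset({"c1", "c2"}),
        )

    def test_assign_group_indices(self):
        sg = self._map()
        assert assign_group("a1", sg) == 1
        assert assign_group("b3", sg) == 2
        assert assign_group("c2", sg) == sg.residual_index == 3

    def test_unknown_label_errors(self):
        with pytest.raises(KeyError, match="'zzz'"):
            assign_group("zzz", self._map())

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            SGMap(
                groups=(SDList("amp", {"a", "b"}), SDList("amp", {"b", "c"})),
                residual=frozenset(),
            )

    def test_singleton_sd_list_rejected(self):
        with pytest.raises(ValueError, match=">=2 members"):
            SDList("amp", {"a"})

    def test_json_round_trip(self, tmp_path):
        sg = self._map()
        sg.to_json(tmp_path / "sg.json")
        back = SGMap.from_json(tmp_path / "sg.json")
        assert back.groups == sg.groups
        assert back.residual == sg.residual
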