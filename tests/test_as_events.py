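"""Route enumeration and AS event classification."""

import numpy as np
import pytest

from circexon.as_events import build_routes, classify_as_events, summarize_frequencies
from circexon.config import RunConfig
from circexon.formats_io import AlignmentSegment, CircEntry
from circexon.fsj_cirexon import Cirexon, FsjCandidate


def fsj(donor, acceptor, support=2, chrom="chr1"):
    reads = {f"r{donor}.{acceptor}.{i}": (1, "+") for i in range(support)}
    return FsjCandidate(chrom, donor, acceptor, "GT-AG", True, reads)


def cx(start, end, chrom="chr1", evidence="fsj-paired"):
    return Cirexon(chrom, start, end, evidence=evidence)


def circ(start=100, end=900, strand="+"):
    return CircEntry(f"chr1:{start}|{end}", "chr1", start, end, strand, {"x", "y"})


@pytest.fixture()
def toy_alt_graph():
    """Cirexons 1, 2a, 2b, 3 where 2a/2b are equivalents sharing their 3'
    boundary, plus a junction skipping both."""
    cirexons = [cx(100, 200), cx(300, 400), cx(320, 400), cx(500, 900)]
    fsjs = [
        fsj(200, 300),  # 1 -> 2a
        fsj(200, 320),  # 1 -> 2b
        fsj(200, 500),  # 1 -> 3 (skip)
        fsj(400, 500),  # 2a/2b -> 3
    ]
    return cirexons, fsjs, circ()


class TestBuildRoutes:
    def test_alternative_cirexon_graph_has_three_routes(self, toy_alt_graph):
        cirexons, fsjs, c = toy_alt_graph
        routes = build_routes(cirexons, fsjs, c)
        chains = sorted(tuple(x.interval for x in r.cirexons) for r in routes)
        assert chains == [
            ((100, 200), (300, 400), (500, 900)),
            ((100, 200), (320, 400), (500, 900)),
            ((100, 200), (500, 900)),
        ]

    def test_single_cirexon_spanning_circle_is_one_route(self):
        routes = build_routes([cx(100, 900)], [], circ())
        assert len(routes) == 1
        assert routes[0].circumference == 801

    def test_chain_of_constitutive_cirexons_is_one_route(self):
        cirexons = [cx(100, 200), cx(300, 400), cx(500, 900)]
        fsjs = [fsj(200, 300), fsj(400, 500)]
        routes = build_routes(cirexons, fsjs, circ())
        assert len(routes) == 1
        assert len(routes[0].cirexons) == 3

    def test_no_route_to_donor_flags_incomplete(self):
        # nothing ends at circ.end
        routes = build_routes([cx(100, 200)], [], circ())
        assert routes == []

    def test_shared_junction_support_summed_per_route(self, toy_alt_graph):
        cirexons, fsjs, c = toy_alt_graph
        routes = build_routes(cirexons, fsjs, c)
        by_len = {tuple(x.interval for x in r.cirexons): r.support_sum for r in routes}
        assert by_len[((100, 200), (300, 400), (500, 900))] == 4  # 2 + 2

    def test_route_count_matches_brute_force_enumeration(self):
        """Independent oracle: recursive path counting over random interval
        DAGs with up to 12 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            bounds = np.sort(rng.choice(np.arange(100, 3000), 2 * n, replace=False))
            nodes = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n)]
            c = CircEntry("chr1:x|y".replace("x", str(nodes[0][0])).replace(
                "y", str(nodes[-1][1])), "chr1", nodes[0][0], nodes[-1][1], "+", {"r"})
            edges = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if nodes[j][0] > nodes[i][1] + 1 and rng.random() < 0.5:
                        edges.add((nodes[i][1], nodes[j][0]))
            fsjs = [fsj(d, a) for d, a in edges]
            routes = build_routes([cx(s, e) for s, e in nodes], fsjs, c)

            def count_paths(i):
                if nodes[i][1] == c.end:
                    return 1
                return sum(
                    count_paths(j)
                    for j in range(i + 1, n)
                    if (nodes[i][1], nodes[j][0]) in edges
                )

            expect = sum(count_paths(i) for i in range(n) if nodes[i][0] == c.start)
            assert len(routes) == expect


def bsj_cover(chrom, start, end):
    return [
        AlignmentSegment("b", 1, chrom, start, "+",
                         (("M", end - start + 1),), 0, end - start + 1, 60,
                         end - start + 1)
    ]


class TestClassify:
    def test_equivalent_skipped_cirexons_are_one_es_group_with_alt_site(self, toy_alt_graph):
        cirexons, fsjs, c = toy_alt_graph
        routes = build_routes(cirexons, fsjs, c)
        (group,) = classify_as_events(routes, cirexons, fsjs, c)
        assert group.event_type == "ES"
        assert "ES" in group.labels
        assert group.labels & {"A5SS", "A3SS"}
        assert sorted(group.members) == [(300, 400), (320, 400)]
        assert not group.nested

    def test_alt_site_label_follows_strand(self, toy_alt_graph):
        cirexons, fsjs, _ = toy_alt_graph
        minus = circ(strand="-")
        routes = build_routes(cirexons, fsjs, minus)
        (group,) = classify_as_events(routes, cirexons, fsjs, minus)
        # members differ at their genomic-left boundary = donor side on '-'
        assert "A5SS" in group.labels

    def test_unknown_strand_reports_unresolved_alt_site(self, toy_alt_graph):
        cirexons, fsjs, _ = toy_alt_graph
        dot = circ(strand=".")
        routes = build_routes(cirexons, fsjs, dot)
        (group,) = classify_as_events(routes, cirexons, fsjs, dot)
        assert "A5SS/A3SS-unresolved" in group.labels

    def test_intron_retention_requires_continuous_bsj_coverage(self):
        cirexons = [cx(100, 300), cx(600, 900)]
        fsjs = [fsj(300, 600)]
        c = circ()
        routes = build_routes(cirexons, fsjs, c)
        covered = classify_as_events(
            routes, cirexons, fsjs, c, bsj_cover("chr1", 100, 900)
        )
        assert [g.event_type for g in covered] == ["IR"]
        assert covered[0].members == [(301, 599)]
        uncovered = classify_as_events(
            routes, cirexons, fsjs, c, bsj_cover("chr1", 100, 300)
        )
        assert uncovered == []

    def test_two_disjoint_skipped_cirexons_are_nested_groups(self):
        cirexons = [cx(100, 150), cx(200, 250), cx(400, 450), cx(600, 900)]
        fsjs = [
            fsj(150, 200), fsj(250, 400), fsj(450, 600),
            fsj(150, 400),  # skips [200,250]
            fsj(250, 600),  # skips [400,450]
        ]
        c = circ()
        routes = build_routes(cirexons, fsjs, c)
        groups = classify_as_events(routes, cirexons, fsjs, c)
        es = [g for g in groups if g.event_type == "ES"]
        assert len(es) == 2
        assert all(g.nested for g in groups)

    def test_classification_invariant_to_cirexon_order(self, toy_alt_graph):
        cirexons, fsjs, c = toy_alt_graph
        a = classify_as_events(build_routes(cirexons, fsjs, c), cirexons, fsjs, c)
        rev = list(reversed(cirexons))
        b = classify_as_events(build_routes(rev, fsjs, c), rev, fsjs, c)
        key = lambda gs: sorted((g.event_type, tuple(sorted(g.members))) for g in gs)
        assert key(a) == key(b)


class TestFrequencies:
    def _groups(self, circ_ids_with_es):
        from circexon.as_events import AsEventGroup

        return {
            cid: [AsEventGroup(cid, "ES", {"ES"}, [(1, 2)])]
            for cid in circ_ids_with_es
        }

    def _entries(self, n, bsj=25):
        return [
            CircEntry(f"chr1:{i * 1000 + 1}|{i * 1000 + 900}", "chr1",
                      i * 1000 + 1, i * 1000 + 900, "+",
                      {f"r{i}.{k}" for k in range(bsj)})
            for i in range(n)
        ]

    def test_fraction_of_hosting_circles(self):
        entries = self._entries(10)
        groups = self._groups([entries[0].circ_id, entries[1].circ_id])
        freqs = summarize_frequencies(groups, entries, min_bsj=20)
        assert freqs["ES"] == 20.0
        assert freqs["IR"] == 0.0

    def test_low_support_circles_excluded_from_denominator(self):
        entries = self._entries(4, bsj=25) + self._entries(1, bsj=3)
        freqs = summarize_frequencies(self._groups([entries[0].circ_id]), entries, 20)
        assert freqs["ES"] == 25.0

    def test_no_groups_means_all_zero(self):
        freqs = summarize_frequencies({}, self._entries(5), 20)
        assert set(freqs.values()) == {0.0}
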