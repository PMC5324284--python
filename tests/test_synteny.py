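"""Ortholog pairing, collinear chaining, miRNA synteny and clusters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from etiomir import synteny
from etiomir.synteny import CollinearBlock, OrthologPair


def _genes(tag, orders, chrom="chr1", gene_len=300, spacing=1000):
    rows = []
    for k, o in enumerate(orders):
        start = 1 + o * spacing
        rows.append(
            {
                "gene_id": f"{tag}_g{k:03d}",
                "chrom": chrom,
                "start": start,
                "end": start + gene_len - 1,
                "order_index": o,
            }
        )
    return pd.DataFrame(rows)


def _pairs(genes_a, genes_b, mapping):
    return [
        OrthologPair(genes_a.gene_id.iloc[i], genes_b.gene_id.iloc[j], 500.0, 1e-50)
        for i, j in mapping
    ]


class TestFindOrthologs:
    def _proteomes(self, rng, n=4, length=80):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        prot_a = {f"a{i}": "".join(rng.choice(aa, size=length)) for i in range(n)}
        prot_b = {}
        for i, (ga, seq) in enumerate(sorted(prot_a.items())):
            s = list(seq)
            for _ in range(8):  # 10% divergence
                p = int(rng.integers(length))
                s[p] = str(rng.choice(aa))
            prot_b[f"b{i}"] = "".join(s)
        return prot_a, prot_b

    def test_one_to_one_orthologs_are_reciprocal_best_hits(self, rng):
        prot_a, prot_b = self._proteomes(rng)
        pairs = synteny.find_orthologs(prot_a, prot_b)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            (f"a{i}", f"b{i}") for i in range(4)
        }
        assert all(p.e_value <= 1e-10 for p in pairs)

    def test_paralog_breaks_reciprocity_for_the_loser(self, rng):
        prot_a, prot_b = self._proteomes(rng, n=3)
        # a duplicate of a0 in A competes for b0; only one can be reciprocal
        prot_a["a0_dup"] = prot_a["a0"][:40] + prot_a["a0"][40:]
        pairs = synteny.find_orthologs(prot_a, prot_b)
        hits_to_b0 = [p for p in pairs if p.gene_b == "b0"]
        assert len(hits_to_b0) == 1

    def test_unrelated_sequences_filtered_by_evalue(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        prot_a = {"a0": "".join(rng.choice(aa, size=60))}
        prot_b = {"b0": "".join(rng.choice(aa, size=60))}
        assert synteny.find_orthologs(prot_a, prot_b) == []

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            synteny.find_orthologs({}, {"b": "MKL"})

    def test_rbh_matches_bruteforce_oracle(self, rng):
        prot_a, prot_b = self._proteomes(rng, n=5)
        prot_a["a0_dup"] = prot_a["a0"]
        pairs = synteny.find_orthologs(prot_a, prot_b, max_evalue=np.inf)
        aligner = synteny._protein_aligner()
        score = {
            (ga, gb): aligner.score(sa, sb)
            for ga, sa in prot_a.items()
            for gb, sb in prot_b.items()
        }
        expected = set()
        for ga in prot_a:
            gb = max(sorted(prot_b), key=lambda x: score[(ga, x)])
            back = max(sorted(prot_a), key=lambda x: score[(x, gb)])
            if back == ga:
                expected.add((ga, gb))
        assert {(p.gene_a, p.gene_b) for p in pairs} == expected


class TestChaining:
    def test_five_in_order_anchors_form_one_block(self):
        ga = _genes("a", range(5))
        gb = _genes("b", range(5))
        blocks = synteny.chain_collinear(_pairs(ga, gb, [(i, i) for i in range(5)]), ga, gb)
        assert len(blocks) == 1 and blocks[0].n_anchors == 5

    def test_four_anchors_are_not_enough(self):
        ga = _genes("a", range(4))
        gb = _genes("b", range(4))
        blocks = synteny.chain_collinear(_pairs(ga, gb, [(i, i) for i in range(4)]), ga, gb)
        assert blocks == []

    def test_ten_insertions_tolerated_eleven_split(self):
        for gap, expect_blocks in [(10, 1), (11, 0)]:
            # 10 anchors; a run of `gap` unanchored genes between anchors 4 and 5
            orders = list(range(5)) + [5 + gap + k for k in range(5)]
            ga = _genes("a", orders)
            gb = _genes("b", orders)
            blocks = synteny.chain_collinear(
                _pairs(ga, gb, [(i, i) for i in range(10)]), ga, gb
            )
            if expect_blocks == 1:
                assert len(blocks) == 1 and blocks[0].n_anchors == 10
                assert blocks[0].max_gap == gap
            else:
                # 11-gene insertion splits the run into two 5-anchor blocks
                assert len(blocks) == 2
                assert all(b.n_anchors == 5 for b in blocks)

    def test_inverted_order_blocks_are_not_chained(self):
        ga = _genes("a", range(5))
        gb = _genes("b", range(5))
        mapping = [(i, 4 - i) for i in range(5)]  # strictly decreasing on B
        assert synteny.chain_collinear(_pairs(ga, gb, mapping), ga, gb) == []

    def test_anchor_exclusivity(self):
        # 9 shared anchors: the 6-anchor chain wins, leaving only 3 for the rest
        ga = _genes("a", range(9))
        gb = _genes("b", range(9))
        blocks = synteny.chain_collinear(
            _pairs(ga, gb, [(i, i) for i in range(9)]), ga, gb, min_anchors=5
        )
        used = [a for b in blocks for a in b.anchors]
        assert len(used) == len(set(used))

    def test_blocks_validate_post_hoc(self, rng):
        ga = _genes("a", range(14))
        gb = _genes("b", range(14))
        blocks = synteny.chain_collinear(
            _pairs(ga, gb, [(i, i) for i in range(14)]), ga, gb
        )
        assert blocks and all(synteny.validate_block(b, ga, gb) for b in blocks)

    def test_validate_block_rejects_broken_invariants(self):
        ga = _genes("a", range(20))
        gb = _genes("b", range(20))
        anchors = [(f"a_g{i:03d}", f"b_g{i:03d}") for i in (0, 1, 2, 3, 15)]
        blk = CollinearBlock("x", anchors, "chr1", "chr1", (1, 2), (1, 2), 11)
        assert not synteny.validate_block(blk, ga, gb)  # gap 11 > 10
        blk2 = CollinearBlock("x", anchors[:4], "chr1", "chr1", (1, 2), (1, 2), 0)
        assert not synteny.validate_block(blk2, ga, gb)  # only 4 anchors


def enumerate_chains_oracle(anchors: pd.DataFrame, max_gap: int) -> set[tuple]:
    """Independent oracle: all source-to-sink paths in the linkability DAG,
    found by filtering every ordered subsequence of the anchor set."""
    idx = list(anchors.index)
    oa, ob = anchors["order_a"].to_dict(), anchors["order_b"].to_dict()

    def ok(i, j):
        return (
            oa[j] > oa[i]
            and ob[j] > ob[i]
            and oa[j] - oa[i] - 1 <= max_gap
            and ob[j] - ob[i] - 1 <= max_gap
        )

    valid = []
    for r in range(1, len(idx) + 1):
        for combo in itertools.permutations(idx, r):
            if all(ok(i, j) for i, j in zip(combo, combo[1:])):
                valid.append(combo)
    # keep only maximal paths: no valid predecessor before, no successor after
    out = set()
    for c in valid:
        if any(ok(j, c[0]) for j in idx):
            continue
        if any(ok(c[-1], j) for j in idx):
            continue
        out.add(c)
    return out


def test_chain_enumeration_matches_oracle_on_random_toys(rng):
    for _ in range(20):
        n = int(rng.integers(2, 8))
        order_a = rng.permutation(20)[:n]
        order_b = rng.permutation(20)[:n]
        anchors = pd.DataFrame(
            {"order_a": order_a, "order_b": order_b},
            index=range(n),
        )
        max_gap = int(rng.integers(0, 11))
        got = {tuple(c) for c in synteny.enumerate_maximal_chains(anchors, max_gap)}
        assert got == enumerate_chains_oracle(anchors, max_gap)


def test_chaining_is_a_to_b_symmetric():
    ga = _genes("a", range(8))
    gb = _genes("b", range(8))
    pairs = _pairs(ga, gb, [(i, i) for i in range(8)])
    fwd = synteny.chain_collinear(pairs, ga, gb)
    swapped = [OrthologPair(p.gene_b, p.gene_a, p.score, p.e_value) for p in pairs]
    rev = synteny.chain_collinear(swapped, gb, ga)
    assert [(b.span_a, b.span_b) for b in fwd] == [(b.span_b, b.span_a) for b in rev]


class TestMiRNASynteny:
    def _blocks(self):
        return [
            CollinearBlock(
                "cb_001", [("a", "b")] * 5, "chr1", "chr2", (1000, 9000), (2000, 9500), 0
            )
        ]

    def _mirna(self, mid, fam, chrom, start, end):
        return pd.DataFrame(
            [{"mirna_id": mid, "family_id": fam, "chrom": chrom, "start": start, "end": end}]
        )

    def test_pair_inside_both_spans_is_syntenic(self):
        calls = synteny.assign_mirna_synteny(
            self._mirna("zm_01_01", "f1", "chr1", 2000, 2200),
            self._mirna("os_02_01", "f1", "chr2", 3000, 3200),
            self._blocks(),
        )
        assert calls[0].syntenic and calls[0].block_id == "cb_001"

    def test_straddling_precursor_is_not_syntenic(self):
        calls = synteny.assign_mirna_synteny(
            self._mirna("zm_01_01", "f1", "chr1", 8900, 9100),  # crosses span end
            self._mirna("os_02_01", "f1", "chr2", 3000, 3200),
            self._blocks(),
        )
        assert not calls[0].syntenic

    def test_family_mismatch_produces_no_call(self):
        calls = synteny.assign_mirna_synteny(
            self._mirna("zm_01_01", "f1", "chr1", 2000, 2200),
            self._mirna("os_02_01", "f2", "chr2", 3000, 3200),
            self._blocks(),
        )
        assert calls == []

    def test_wrong_chromosome_is_not_syntenic(self):
        calls = synteny.assign_mirna_synteny(
            self._mirna("zm_01_01", "f1", "chr2", 2000, 2200),
            self._mirna("os_02_01", "f1", "chr2", 3000, 3200),
            self._blocks(),
        )
        assert not calls[0].syntenic

    def test_family_summary_ors_over_pairs(self):
        calls = [
            synteny.MiRNASyntenyCall("a", "b", "f1", None, False),
            synteny.MiRNASyntenyCall("c", "d", "f1", "cb_001", True),
            synteny.MiRNASyntenyCall("e", "f", "f2", None, False),
        ]
        assert synteny.syntenic_family_summary(calls) == {"f1": True, "f2": False}


class TestClusters:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["mirna_id", "family_id", "chrom", "start", "end"]
        )

    def test_two_members_within_10kb_cluster(self):
        m = self._frame(
            [("m1", "f", "chr1", 1000, 1200), ("m2", "f", "chr1", 6000, 6200)]
        )
        assert synteny.detect_clusters(m) == [["m1", "m2"]]

    def test_members_beyond_10kb_do_not_cluster(self):
        m = self._frame(
            [("m1", "f", "chr1", 1000, 1200), ("m2", "f", "chr1", 12_000, 12_200)]
        )
        assert synteny.detect_clusters(m) == []

    def test_single_linkage_is_transitive(self):
        m = self._frame(
            [
                ("m1", "f", "chr1", 1000, 1200),
                ("m2", "f", "chr1", 9000, 9200),
                ("m3", "f", "chr1", 17_000, 17_200),  # >10kb from m1, <10kb from m2
            ]
        )
        assert synteny.detect_clusters(m) == [["m1", "m2", "m3"]]

    def test_matches_union_find_oracle(self, rng):
        n = 25
        starts = np.sort(rng.integers(0, 200_000, size=n))
        m = self._frame(
            [(f"m{i}", "f", "chr1", int(s), int(s) + 150) for i, s in enumerate(starts)]
        )
        got = synteny.detect_clusters(m)
        # union-find oracle on the same gap rule
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(n - 1):
            if starts[i + 1] - (starts[i] + 150) <= 10_000:
                parent[find(i + 1)] = find(i)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(f"m{i}")
        expected = [g for g in groups.values() if len(g) >= 2]
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))

    def test_different_families_never_cluster(self):
        m = self._frame(
            [("m1", "f1", "chr1", 1000, 1200), ("m2", "f2", "chr1", 2000, 2200)]
        )
        assert synteny.detect_clusters(m) == []


def test_end_to_end_planted_blocks_and_synteny(small_truth):
    proteomes = {
        sp: {
            r.gene_id: synteny.translate_cds(r.cds)
            for r in small_truth.genes[sp].itertuples()
        }
        for sp in ("zm", "os")
    }
    pairs = synteny.find_orthologs(proteomes["zm"], proteomes["os"])
    planted = set(small_truth.ortholog_pairs)
    found = {(p.gene_a, p.gene_b) for p in pairs}
    assert planted <= found
    blocks = synteny.chain_collinear(pairs, small_truth.genes["zm"], small_truth.genes["os"])
    recoverable = [b for b in small_truth.intended_blocks if b["recoverable"]]
    assert len(blocks) >= len(recoverable)
    # every planted recoverable block is found with all of its anchors
    for intended in recoverable:
        anchors = set(intended["anchors"])
        assert any(anchors <= set(b.anchors) for b in blocks)
    # planted miRNAs were placed within blocks: every family gets a syntenic call
    mir_frames = {}
    for sp in ("zm", "os"):
        mir_frames[sp] = pd.DataFrame(
            [
                {
                    "mirna_id": m.mirna_id,
                    "family_id": m.family_id,
                    "chrom": m.chrom,
                    "start": m.start,
                    "end": m.end,
                }
                for m in small_truth.mirnas[sp]
            ]
        )
    calls = synteny.assign_mirna_synteny(mir_frames["zm"], mir_frames["os"], blocks)
    summary = synteny.syntenic_family_summary(calls)
    assert summary and all(summary.values())


def test_read_hit_table_keeps_best_per_query(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\ts1\t98.0\t100\t2\t0\t1\t100\t1\t100\t1e-50\t200\n"
        "q1\ts2\t80.0\t100\t20\t0\t1\t100\t1\t100\t1e-20\t90\n"
        "q2\ts3\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-40\t180\n"
    )
    pairs = synteny.read_hit_table(path)
    assert {(p.gene_a, p.gene_b) for p in pairs} == {("q1", "s1"), ("q2", "s3")}


def test_circos_links_and_blocks_table(tmp_path):
    blk = CollinearBlock("cb_001", [("a", "b")] * 5, "chr1", "chr2", (10, 90), (20, 80), 3)
    path = tmp_path / "links.txt"
    synteny.write_circos_links(path, [blk])
    assert path.read_text() == "chr1\t10\t90\tchr2\t20\t80\n"
    table = synteny.blocks_table([blk])
    assert table.loc[0, "n_anchors"] == 5 and table.loc[0, "span_a"] == "10-90"
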