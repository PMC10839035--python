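"""A-tract masking, poly(A)-site clustering, zoning, nonstop fractions."""

import re

import numpy as np
import pytest

from pacvar.patseq import (
    ANTISENSE,
    CDS_INTERNAL,
    FIVE_PRIME,
    INTERGENIC,
    INTRONIC,
    THREE_PRIME,
    PolyASiteCall,
    TagAlignment,
    build_a_mask,
    classify_site,
    cluster_sites,
    filter_tags,
    gene_nonstop_table,
    nonstop_fraction,
    read_bed6,
    write_bed6,
)

from conftest import random_cds, synthetic_gene


def regex_mask_oracle(seq, base, min_run, flank, left_flank):
    """Brute-force scan: maskable positions for runs of `base` >= min_run."""
    masked = set()
    for m in re.finditer(f"{base}{{{min_run},}}", seq):
        s, e = m.start() + 1, m.end()  # 1-based inclusive
        if left_flank:
            masked.update(range(max(1, s - flank), e + 1))
        else:
            masked.update(range(s, min(len(seq), e + flank) + 1))
    return masked


def test_mask_covers_a_tract_and_upstream_flank():
    genome = {"c": "C" * 50 + "A" * 10 + "C" * 50}
    mask = build_a_mask(genome, min_run=8, flank=20)
    assert mask.contains("c", "+", 55)   # tract itself
    assert mask.contains("c", "+", 31)   # 20 nt upstream
    assert not mask.contains("c", "+", 30)
    assert not mask.contains("c", "+", 61)  # downstream of tract
    assert not mask.contains("c", "-", 55)  # A-run masks + tags only


def test_run_below_threshold_not_masked():
    mask = build_a_mask({"c": "C" * 50 + "A" * 7 + "C" * 50}, min_run=8)
    assert not mask.contains("c", "+", 55)


def test_mask_matches_regex_oracle(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    # salt with some runs
    seq = seq[:500] + "A" * 9 + seq[500:1500] + "T" * 12 + seq[1500:]
    mask = build_a_mask({"c": seq}, min_run=8, flank=15)
    plus = regex_mask_oracle(seq, "A", 8, 15, left_flank=True)
    minus = regex_mask_oracle(seq, "T", 8, 15, left_flank=False)
    for pos in range(1, len(seq) + 1):
        assert mask.contains("c", "+", pos) == (pos in plus)
        assert mask.contains("c", "-", pos) == (pos in minus)


def test_masking_monotone_in_min_run(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
    seq += "A" * 10 + "T" * 9
    sets = []
    for min_run in (6, 8, 10, 11):
        mask = build_a_mask({"c": seq}, min_run=min_run)
        sets.append({
            (st, p) for st in "+-" for p in range(1, len(seq) + 1)
            if mask.contains("c", st, p)
        })
    for bigger, smaller in zip(sets, sets[1:]):
        assert smaller <= bigger  # increasing min_run never enlarges the mask


def test_cluster_examples():
    tags = [TagAlignment("c", "+", p) for p in (100, 101, 103)]
    (site,) = cluster_sites(tags, merge_window=24)
    assert site.tag_count == 3
    assert site.position == 100  # modal tie broken by smallest

    sites = cluster_sites(
        [TagAlignment("c", "+", 100), TagAlignment("c", "+", 200)], 24
    )
    assert len(sites) == 2


def cluster_oracle(ends, window):
    """O(n^2) single-linkage via union-find."""
    parent = list(range(len(ends)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ends)):
        for j in range(i + 1, len(ends)):
            if abs(ends[i] - ends[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(ends)):
        groups.setdefault(find(i), []).append(ends[i])
    return sorted(sorted(g) for g in groups.values())


def test_clustering_matches_union_find_oracle(rng):
    ends = [int(p) for p in rng.integers(1, 5000, size=600)]
    tags = [TagAlignment("c", "+", p) for p in ends]
    sites = cluster_sites(tags, merge_window=24)
    got = sorted(
        sorted(
            e for e in ends_in_cluster
        ) for ends_in_cluster in _cluster_members(tags, sites)
    )
    assert got == cluster_oracle(ends, 24)
    # conservation: every unmasked tag is in exactly one cluster
    assert sum(s.tag_count for s in sites) == len(tags)


def _cluster_members(tags, sites):
    """Recover cluster membership from sorted ends and cluster sizes."""
    ends = sorted(t.three_prime_end for t in tags)
    sites = sorted(sites, key=lambda s: min(e for e in ends))
    # clusters are contiguous in sorted order for single-linkage on a line
    out, i = [], 0
    for s in sorted(sites, key=lambda s: s.position):
        out.append(ends[i: i + s.tag_count])
        i += s.tag_count
    return out


@pytest.mark.parametrize("strand", ["+", "-"])
def test_zone_classification_examples(rng, strand):
    cds = random_cds(rng, 60)
    model, _ = synthetic_gene(cds, strand=strand, exon_lens=[90, 90],
                              left=1001, pad=1000)

    def site(pos, st=strand):
        return PolyASiteCall(model.chrom, st, pos, 1)

    stop = model.stop_genomic_pos
    sign = 1 if strand == "+" else -1
    assert classify_site(site(stop - sign * 50), model) == CDS_INTERNAL
    assert classify_site(site(stop + sign * 100), model, 300) == THREE_PRIME
    assert classify_site(site(stop + sign * 400), model, 300) == INTERGENIC
    start = model.cds_segments[0][0] if strand == "+" else model.cds_segments[0][1]
    assert classify_site(site(start - sign * 10), model) == FIVE_PRIME
    intron_pos = (model.cds_segments[0][1] + 1 if strand == "+"
                  else model.cds_segments[0][0] - 1)
    assert classify_site(site(intron_pos), model) == INTRONIC
    opposite = "-" if strand == "+" else "+"
    assert classify_site(site(stop - sign * 50, opposite), model) == ANTISENSE


def test_zone_matches_interval_membership_oracle(rng):
    cds = random_cds(rng, 40)
    model, _ = synthetic_gene(cds, exon_lens=[60, 60], left=1001, pad=1000)
    lo, hi = model.cds_span
    coding = {model.cds_to_genomic(o) for o in range(1, len(cds) + 1)}
    for pos in range(lo - 600, hi + 601, 7):
        zone = classify_site(PolyASiteCall("chr1", "+", pos, 1), model, 500, 500)
        if pos in coding:
            expected = CDS_INTERNAL
        elif lo <= pos <= hi:
            expected = INTRONIC
        elif hi < pos <= hi + 500:
            expected = THREE_PRIME
        elif lo - 500 <= pos < lo:
            expected = FIVE_PRIME
        else:
            expected = INTERGENIC
        assert zone == expected, pos


def test_nonstop_fraction_edges():
    def s(zone, count):
        return PolyASiteCall("c", "+", 1, count, zone=zone, gene_id="g")

    assert nonstop_fraction([s(THREE_PRIME, 10)]) == 0.0
    assert nonstop_fraction([s(CDS_INTERNAL, 10)]) == 1.0
    assert nonstop_fraction([s(CDS_INTERNAL, 7), s(THREE_PRIME, 3)]) == 0.7
    assert nonstop_fraction([s(ANTISENSE, 5)]) is None  # missing, not 0


def test_bed6_round_trip(tmp_path, rng):
    tags = [
        TagAlignment("chr1", "+-"[int(rng.integers(0, 2))],
                     int(rng.integers(1, 10_000)), f"s{int(rng.integers(1, 4))}")
        for _ in range(50)
    ]
    path = tmp_path / "tags.bed"
    write_bed6(tags, str(path))
    back = read_bed6(str(path))
    assert back == tags
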