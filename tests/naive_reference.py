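"""Brute-force reference for the pair catalog, used only by the tests.

Implements the three catalog rules (coordinate overlap join, opposite-strand
filter, longest-ncRNA-per-gene with the smaller-start / lexicographic-id
tie-break) as a plain O(n*m) double loop with no shared code or data
structures with the package implementation.
"""

from __future__ import annotations


def naive_catalog(genes, ncrnas):
    """Return {gene_id: (ncrna_id, overlap_start, overlap_end)} per the rules."""
    candidates = []
    for g in genes:
        for n in ncrnas:
            if g.chrom != n.chrom:
                continue
            lo = max(g.start, n.start)
            hi = min(g.end, n.end)
            if lo > hi:
                continue
            candidates.append((g, n, lo, hi))

    opposite = [(g, n, lo, hi) for g, n, lo, hi in candidates if g.strand != n.strand]

    best: dict[str, tuple] = {}
    for g, n, lo, hi in opposite:
        nlen = n.end - n.start + 1
        key = (-nlen, n.start, n.feature_id)
        if g.feature_id not in best or key < best[g.feature_id][0]:
            best[g.feature_id] = (key, n.feature_id, lo, hi)
    resolved = {gid: rec[1:] for gid, rec in best.items()}
    counts = {
        "n_candidate_pairs": len(candidates),
        "n_opposite_pairs": len(opposite),
        "n_catalog_pairs": len(resolved),
    }
    return resolved, counts


def random_instance(rng, max_genes=500, max_ncrnas=1000, chroms=("c1", "c2", "c3")):
    """A random gene/ncRNA instance as lists of simple records."""
    from antisense_pairs.annotations import FeatureSet, GenomicFeature

    n_g = int(rng.integers(1, max_genes + 1))
    n_n = int(rng.integers(1, max_ncrnas + 1))

    def draw(prefix, count, kind):
        feats = []
        for i in range(count):
            start = int(rng.integers(1, 50_000))
            length = int(rng.integers(1, 2_000))
            feats.append(
                GenomicFeature(
                    f"{prefix}{i}",
                    str(rng.choice(chroms)),
                    start,
                    start + length - 1,
                    str(rng.choice(["+", "-"])),
                    kind=kind,
                )
            )
        return feats

    return (
        FeatureSet(draw("g", n_g, "gene"), label="genes"),
        FeatureSet(draw("n", n_n, "ncRNA_other"), label="ncRNAs"),
    )
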