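"""Literal brute-force reference implementations.

Deliberately naive (explicit loops over every pair / genotype / site) and
independent of the library's vectorized code paths; used to cross-check
the filtering operations on small fixtures.
"""

from __future__ import annotations

def brute_pairwise_filter(rpkm_dict, producers, nonproducers, fold, pseudocount):
    """All-pairs fold exclusion, gene by gene, pair by pair.

    ``rpkm_dict``: {gene: {genotype: rpkm}}.  Returns the set of surviving
    gene ids.
    """
    survivors = set()
    for gene, row in rpkm_dict.items():
        ok = True
        for p in producers:
            for q in nonproducers:
                ratio = (row[p] + pseudocount) / (row[q] + pseudocount)
                if not ratio > fold:
                    ok = False
        if ok:
            survivors.add(gene)
    return survivors


def brute_presence_screen(rpkm_dict, producers, nonproducers, detect_threshold):
    """Genes detected in every producer and in no non-producer."""
    kept = set()
    for gene, row in rpkm_dict.items():
        if all(row[p] > detect_threshold for p in producers) and all(
            not (row[q] > detect_threshold) for q in nonproducers
        ):
            kept.add(gene)
    return kept


def brute_parental_comparison(rpkm_dict, a, b, min_rpkm, fold, detect):
    unique_a, unique_b, over_a, over_b = set(), set(), set(), set()
    for gene, row in rpkm_dict.items():
        ra, rb = row[a], row[b]
        if not (ra > min_rpkm or rb > min_rpkm):
            continue
        da, db = ra > detect, rb > detect
        if da and not db:
            unique_a.add(gene)
        if db and not da:
            unique_b.add(gene)
        if da and db:
            if ra >= fold * rb:
                over_a.add(gene)
            if rb >= fold * ra:
                over_b.add(gene)
    return unique_a, unique_b, over_a, over_b


def brute_filter_snps(sites, min_frac, min_depth, min_genotypes):
    """Triple loop over sites, genotypes and criteria.

    ``sites``: list of (chrom, pos, {genotype: (depth, nonref)}).
    Returns list of (chrom, pos, frozenset(passing)).
    """
    out = []
    for chrom, pos, obs in sites:
        passing = set()
        for gid, (depth, nonref) in obs.items():
            if depth >= min_depth:
                if depth > 0 and nonref / depth >= min_frac:
                    passing.add(gid)
        if len(passing) >= min_genotypes:
            out.append((chrom, pos, frozenset(passing)))
    return out


def brute_concordance(marker_by_genotype, producer_by_genotype):
    """Element-wise comparison over the shared genotype set."""
    shared = sorted(set(marker_by_genotype) & set(producer_by_genotype))
    agree = 0
    discordant = []
    for g in shared:
        if marker_by_genotype[g] == producer_by_genotype[g]:
            agree += 1
        else:
            discordant.append(g)
    return agree / len(shared), discordant


def trend_oracle(v1, v2, v3, floor, rel_tol):
    """Rule-table classifier written straight from the class definitions."""
    if max(v1, v2, v3) <= floor:
        return "NONPRODUCER"
    gap = rel_tol * max(v1, v2, v3)
    if v2 - v1 > gap and v2 - v3 > gap:
        return "PEAK"
    if v1 - v2 > gap and v3 - v2 > gap:
        return "VALLEY"
    if v1 - v2 > gap and v1 - v3 > gap and abs(v2 - v3) <= gap:
        return "DECREASE"
    if v3 - v2 > gap and v2 - v1 > gap:
        return "INCREASE"
    if v2 >= v1 and v2 >= v3:
        return "PEAK"
    if v1 >= v2 and v1 >= v3:
        return "DECREASE"
    return "INCREASE"
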