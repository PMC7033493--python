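"""Shared test helpers: independent oracles and small cohort configs.

Everything here is deliberately written from first principles (plain Python,
math.comb, explicit codon table) so it stays independent of the package code
paths it checks.
"""

from __future__ import annotations

import math
from collections import defaultdict

from editscan.simulate import SimulationConfig

# ---------------------------------------------------------------------------
# cohort configs
# ---------------------------------------------------------------------------


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale cohort for fast unit tests."""
    base = dict(
        seed=seed, n_tumor=16, n_normal=8, n_paired=6, n_genes=16,
        n_sites=260, n_gain=12, n_loss=12, n_dys=6, n_expression_linked=4,
        n_survival_linked=3, n_snp_overlap=8, n_snp_extra=10,
        n_mutation_overlap=8, n_artifact_100pct=6, n_artifact_lowcov=6,
        n_artifact_quality=5, n_artifact_lowspread=5, n_dual_strand=5,
        n_noncanonical=5, n_indel=4, n_mirna=8, n_mirna_gain=2, n_mirna_loss=1,
        n_extra_mutations_per_sample=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# filter-cascade oracle: single-pass brute force over plain dicts
# ---------------------------------------------------------------------------


def manual_quantile(values, q: float) -> float:
    """Linear-interpolation quantile on the sorted vector (own arithmetic)."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    h = q * (len(v) - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_force_cascade(obs_df, mutations_df, snp_positions, n_samples,
                        max_fs=20.0, min_qd=2.0, min_alt=2, min_cov=10,
                        min_spread=0.10, recurrence_fraction=0.01,
                        canonical=None):
    """Independent single-pass filter: returns the surviving observation keys
    (sample, chrom, pos, ref, alt)."""
    muts = set(zip(mutations_df["sample"], mutations_df["chrom"],
                   mutations_df["pos"]))
    survivors = []
    for row in obs_df.itertuples(index=False):
        if (row.sample, row.chrom, row.pos) in muts:
            continue
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue
        if (row.chrom, row.pos) in snp_positions:
            continue
        fs = None if row.fs != row.fs else row.fs  # NaN check
        qd = None if row.qd != row.qd else row.qd
        cov = row.ref_reads + row.alt_reads
        if fs is not None and fs > max_fs:
            continue
        if qd is not None and qd < min_qd:
            continue
        if row.alt_reads < min_alt or cov < min_cov:
            continue
        if row.ref_reads == 0:  # 100% editing degree
            continue
        if canonical is not None and row.chrom not in canonical:
            continue
        survivors.append(row)
    by_site = defaultdict(list)
    for row in survivors:
        by_site[(row.chrom, row.pos, row.ref, row.alt)].append(row)
    keep = set()
    for key, rows in by_site.items():
        degrees = [r.alt_reads / (r.alt_reads + r.ref_reads) for r in rows]
        vec = degrees + [0.0] * (n_samples - len(degrees))
        if manual_quantile(vec, 0.90) - manual_quantile(vec, 0.10) < min_spread:
            continue
        if len([d for d in degrees if d > 0]) < math.ceil(
                recurrence_fraction * n_samples):
            continue
        for r in rows:
            keep.add((r.sample, r.chrom, r.pos, r.ref, r.alt))
    return keep


def cascade_keys(obs_df):
    return set(zip(obs_df["sample"], obs_df["chrom"], obs_df["pos"],
                   obs_df["ref"], obs_df["alt"]))


# ---------------------------------------------------------------------------
# translation oracle with an explicit codon table
# ---------------------------------------------------------------------------

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def translate(cds: str) -> str:
    return "".join(_CODONS[cds[i:i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


def brute_force_consequence(cds_seq: str, idx: int, sense_alt: str) -> tuple[str, str]:
    """Classify an edit at coding position ``idx`` by translating the full
    reference and edited CDS and comparing the protein strings."""
    edited = cds_seq[:idx] + sense_alt + cds_seq[idx + 1:]
    p_ref, p_alt = translate(cds_seq), translate(edited)
    i = idx // 3
    a, b = p_ref[i], p_alt[i]
    assert all(x == y for j, (x, y) in enumerate(zip(p_ref, p_alt)) if j != i)
    aa = f"{a}{i + 1}{b}"
    if a == b:
        return "synonymous", aa
    if b == "*":
        return "stop_gain", aa
    if a == "*":
        return "stop_loss", aa
    return "non-synonymous", aa


# ---------------------------------------------------------------------------
# exact combinatorial oracles
# ---------------------------------------------------------------------------


def fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by enumerating all tables
    with the same margins and summing probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def hypergeom_upper_tail(overlap, universe, term, query) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    total = math.comb(universe, query)
    lo = overlap
    hi = min(term, query)
    return sum(math.comb(term, k) * math.comb(universe - term, query - k)
               for k in range(lo, hi + 1)) / total


def paired_t_pvalue(diffs) -> float:
    """Textbook paired t: t = mean / (sd / sqrt(n)); two-sided p via scipy's
    t survival function (distribution only, the statistic is hand-built)."""
    from scipy.stats import t as t_dist

    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    return 2 * t_dist.sf(abs(t), n - 1)


# ---------------------------------------------------------------------------
# duplex-alignment oracle: ungapped offsets plus single-gap placements
# ---------------------------------------------------------------------------

_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_score(m, w, params, mir_pos_1based):
    if (m, w) in _PAIR:
        s = params.wc_reward
    elif (m, w) in _WOBBLE:
        s = params.gu_reward
    else:
        s = params.mismatch
    if params.seed_start <= mir_pos_1based <= params.seed_end:
        s *= params.seed_multiplier
    return s


def _seg_best(scores) -> float:
    """Best-scoring contiguous run (local alignment trims both ends)."""
    best = run = 0.0
    for s in scores:
        run = max(0.0, run + s)
        best = max(best, run)
    return best


def oracle_best_score(mirna: str, window: str, params) -> float:
    """Best local alignment raw score over all ungapped offsets plus every
    single length-1 gap placement in either sequence."""
    mir_rev = mirna[::-1]
    m, n = len(mir_rev), len(window)

    def pscore(mi, wi):
        return _pair_score(mir_rev[mi], window[wi], params, m - mi)

    candidates = []
    for off in range(-m, n + 1):
        # ungapped register
        candidates.append([pscore(i, off + i) for i in range(m)
                           if 0 <= off + i < n])
        for g in range(1, m):
            # one unpaired window base after g miRNA bases (gap in miRNA axis)
            aln = [pscore(i, off + i) for i in range(g) if 0 <= off + i < n]
            aln.append(params.gap_open)
            aln += [pscore(i, off + i + 1) for i in range(g, m)
                    if 0 <= off + i + 1 < n]
            candidates.append(aln)
            # one bulged miRNA base g (gap in window axis)
            aln = [pscore(i, off + i) for i in range(g) if 0 <= off + i < n]
            aln.append(params.gap_open)
            aln += [pscore(i, off + i - 1) for i in range(g + 1, m)
                    if 0 <= off + i - 1 < n]
            candidates.append(aln)
    return max(_seg_best(c) for c in candidates)


def oracle_full_score(mirna: str, window: str, params) -> float:
    """Exhaustive local-alignment oracle over the full gapped search space,
    written as a pair-ending recursion with explicit gap-length enumeration
    (structurally unlike the three-state affine DP it checks)."""
    import functools

    mir_rev = mirna[::-1]
    m, n = len(mir_rev), len(window)

    @functools.lru_cache(maxsize=None)
    def end_pair(i, j):
        """Best score of any local alignment ending with the pair (i, j)."""
        s = _pair_score(mir_rev[i], window[j], params, m - i)
        best_prev = 0.0
        if i > 0 and j > 0:
            best_prev = max(best_prev, end_pair(i - 1, j - 1))
            for k in range(1, i):  # k unpaired miRNA bases before this pair
                gap = params.gap_open + params.gap_extend * (k - 1)
                best_prev = max(best_prev, end_pair(i - 1 - k, j - 1) + gap)
            for k in range(1, j):  # k unpaired window bases before this pair
                gap = params.gap_open + params.gap_extend * (k - 1)
                best_prev = max(best_prev, end_pair(i - 1, j - 1 - k) + gap)
        return best_prev + s

    best = 0.0
    for i in range(m):
        for j in range(n):
            best = max(best, end_pair(i, j))
    return best
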