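"""miRNA-target rewiring by 3'UTR editing.

For every editing site in a 3'UTR the reference and edited 101-nt windows
(50 nt of flank each side, truncated at transcript ends) are scored against
the mature-miRNA catalog with a miRanda-style engine: a local
dynamic-programming alignment of the reversed miRNA against the window over a
complementarity scoring scheme (Watson-Crick pair +5, G:U wobble +2, mismatch
-3, seed positions 2-8 of the miRNA doubled, affine gaps open -4 / extend -9,
overall scale 1.25 so a perfect ~22-nt duplex scores ~181), and a
nearest-neighbour stack-energy model for the duplex free energy (Turner-like
Watson-Crick stack table, wobble stacks approximated at -1.0 kcal/mol,
+4.1 kcal/mol duplex initiation; unpaired and gapped positions contribute 0).

A miRNA-window pair is a hit when score > 140 and deltaG < -14 kcal/mol.  Per
miRNA and site: hit on the reference window only -> *edited loss*; on the
edited window only -> *edited gain*; on both with |deltadeltaG| > 14 kcal/mol
-> *edited change*.  A site with more than 10 such regulation changes carries
a miRNA-target regulation consequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

from .annotate import revcomp, spliced_sequence, transcript_coord
from .formats import GeneModel

__all__ = ["DuplexParams", "TargetWindow", "DuplexHit", "RegulationChange",
           "build_windows", "best_alignment", "score_duplex",
           "classify_regulation_change", "call_mirna_consequence",
           "rewire_sites", "duplex_free_energy"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class DuplexParams:
    wc_reward: float = 5.0
    gu_reward: float = 2.0
    mismatch: float = -3.0
    seed_multiplier: float = 2.0
    seed_start: int = 2  # miRNA positions (1-based, from the 5' end)
    seed_end: int = 8
    gap_open: float = -4.0
    gap_extend: float = -9.0
    scale: float = 1.25
    score_threshold: float = 140.0
    dg_threshold: float = -14.0  # kcal/mol
    ddg_threshold: float = 14.0  # kcal/mol, |deltadeltaG| for edited_change
    min_mirna_length: int = 15
    flank: int = 50


@dataclass
class TargetWindow:
    site_id: str
    transcript_id: str
    ref_seq: str
    edited_seq: str
    center: int  # index of the edited base within the window

    def __post_init__(self) -> None:
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.edited_seq))
                 if a != b]
        if diffs != [self.center] or len(self.ref_seq) != len(self.edited_seq):
            raise ValueError("windows must differ exactly at the center position")


@dataclass
class DuplexHit:
    mirna: str
    score: float
    dg: float  # kcal/mol
    window_start: int  # leftmost aligned window position
    window_end: int
    pairs: list[tuple[int, int]] = field(repr=False, default_factory=list)


@dataclass(frozen=True)
class RegulationChange:
    site_id: str
    mirna: str
    kind: str  # edited_gain | edited_loss | edited_change
    ddg: float | None = None  # deltaG_edited - deltaG_ref for edited_change


# ---------------------------------------------------------------------------
# Alignment engine
# ---------------------------------------------------------------------------

def _pair_matrix(params: DuplexParams) -> np.ndarray:
    """P[mirna_base, window_base]; DNA codes, wobble = G:T in DNA alphabet."""
    p = np.full((4, 4), params.mismatch)
    for a, b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        p[_CODE[a], _CODE[b]] = params.wc_reward
    for a, b in (("G", "T"), ("T", "G")):
        p[_CODE[a], _CODE[b]] = params.gu_reward
    return p


@njit(cache=False)
def _align(mir: np.ndarray, win: np.ndarray, pair: np.ndarray,
           seed_mult: np.ndarray, gap_open: float, gap_extend: float):
    """Affine-gap local alignment; returns (raw score, miRNA idx, window idx,
    n aligned pairs).  ``mir`` is the reversed miRNA; ``seed_mult`` is the
    per-row multiplier for the reversed orientation."""
    m, n = len(mir), len(win)
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in window (consumes miRNA base)
    Y = np.full((m + 1, n + 1), NEG)  # gap in miRNA (consumes window base)
    ptr_m = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 start,1 M,2 X,3 Y
    ptr_x = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_y = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0.0
    bi = bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = pair[mir[i - 1], win[j - 1]] * seed_mult[i - 1]
            prev = 0.0
            p = 0
            if M[i - 1, j - 1] > prev:
                prev, p = M[i - 1, j - 1], 1
            if X[i - 1, j - 1] > prev:
                prev, p = X[i - 1, j - 1], 2
            if Y[i - 1, j - 1] > prev:
                prev, p = Y[i - 1, j - 1], 3
            M[i, j] = prev + s
            ptr_m[i, j] = p
            # gap states (never open from nothing: require a real prefix)
            xo = M[i - 1, j] + gap_open
            xe = X[i - 1, j] + gap_extend
            if xo >= xe:
                X[i, j], ptr_x[i, j] = xo, 1
            else:
                X[i, j], ptr_x[i, j] = xe, 2
            yo = M[i, j - 1] + gap_open
            ye = Y[i, j - 1] + gap_extend
            if yo >= ye:
                Y[i, j], ptr_y[i, j] = yo, 1
            else:
                Y[i, j], ptr_y[i, j] = ye, 3
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    out_i = np.empty(m + n, dtype=np.int64)
    out_j = np.empty(m + n, dtype=np.int64)
    count = 0
    state = 1
    i, j = bi, bj
    if best <= 0.0:
        return 0.0, out_i, out_j, 0
    while i > 0 and j > 0:
        if state == 1:
            out_i[count] = i - 1
            out_j[count] = j - 1
            count += 1
            nxt = ptr_m[i, j]
            i -= 1
            j -= 1
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            nxt = ptr_x[i, j]
            i -= 1
            state = nxt
        else:
            nxt = ptr_y[i, j]
            j -= 1
            state = nxt
    return best, out_i, out_j, count


# Turner-like RNA/RNA Watson-Crick stack energies (kcal/mol), keyed by the
# 5'->3' target dinucleotide when both positions are WC-paired.  Written in
# the DNA alphabet used internally (U == T).  Approximate by design.
_WC_STACK = {
    ("A", "A"): -0.93, ("A", "T"): -1.10, ("T", "A"): -1.33,
    ("C", "T"): -2.08, ("C", "A"): -2.11, ("G", "T"): -2.24,
    ("G", "A"): -2.35, ("C", "G"): -2.36, ("G", "G"): -3.26,
    ("G", "C"): -3.42, ("A", "C"): -2.24, ("A", "G"): -2.08,
    ("T", "C"): -2.35, ("T", "G"): -2.11, ("T", "T"): -0.93,
    ("C", "C"): -3.26,
}
_WOBBLE_STACK = -1.0
_DUPLEX_INIT = 4.1

_WC_SET = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU_SET = {("G", "T"), ("T", "G")}


def duplex_free_energy(window: str, mirna: str,
                       pairs: list[tuple[int, int]]) -> float:
    """Nearest-neighbour deltaG of an aligned duplex.

    ``pairs`` holds (window index, miRNA index) of aligned positions, with the
    miRNA index counted on the *reversed* miRNA.  Adjacent aligned pairs that
    are both WC or wobble contribute a stack term; anything else contributes
    nothing.  Duplex initiation costs +4.1 kcal/mol.
    """
    if not pairs:
        return 0.0
    mir_rev = mirna[::-1]
    ordered = sorted(pairs)
    dg = _DUPLEX_INIT
    for (w1, m1), (w2, m2) in zip(ordered, ordered[1:]):
        if w2 != w1 + 1 or m2 != m1 + 1:
            continue  # interrupted by gap/mismatch skip: no stack
        p1 = (window[w1], mir_rev[m1])
        p2 = (window[w2], mir_rev[m2])
        if p1 in _WC_SET and p2 in _WC_SET:
            dg += _WC_STACK[(window[w1], window[w2])]
        elif (p1 in _WC_SET | _GU_SET) and (p2 in _WC_SET | _GU_SET):
            dg += _WOBBLE_STACK
    return dg


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 0) for c in seq), dtype=np.int8, count=len(seq))


def best_alignment(mirna_seq: str, window_seq: str,
                   params: DuplexParams = DuplexParams(),
                   ) -> tuple[float, list[tuple[int, int]]]:
    """Raw (unscaled) local alignment score and the aligned (window index,
    reversed-miRNA index) pairs."""
    mir_rev = _encode(mirna_seq[::-1])
    win = _encode(window_seq)
    m = len(mir_rev)
    seed_mult = np.ones(m)
    for i in range(m):
        pos = m - i  # original 1-based miRNA position from the 5' end
        if params.seed_start <= pos <= params.seed_end:
            seed_mult[i] = params.seed_multiplier
    raw, pi, pj, cnt = _align(mir_rev, win, _pair_matrix(params), seed_mult,
                              params.gap_open, params.gap_extend)
    return float(raw), [(int(pj[k]), int(pi[k])) for k in range(cnt)]


def score_duplex(mirna_seq: str, window_seq: str,
                 params: DuplexParams = DuplexParams(),
                 mirna_name: str = "") -> DuplexHit | None:
    """Score one miRNA against one window; None unless both the score and the
    free-energy gates pass."""
    if len(mirna_seq) < params.min_mirna_length:
        raise ValueError(f"miRNA shorter than {params.min_mirna_length} nt")
    raw, pairs = best_alignment(mirna_seq, window_seq, params)
    score = raw * params.scale
    if score <= params.score_threshold:
        return None
    dg = duplex_free_energy(window_seq, mirna_seq, pairs)
    if not dg < params.dg_threshold:
        return None
    wpos = [w for w, _ in pairs]
    return DuplexHit(mirna=mirna_name, score=float(score), dg=float(dg),
                     window_start=min(wpos), window_end=max(wpos) + 1,
                     pairs=sorted(pairs))


# ---------------------------------------------------------------------------
# Window construction and classification
# ---------------------------------------------------------------------------

def build_windows(site_id: str, pos: int, ref: str, alt: str, gene: GeneModel,
                  genome: dict[str, str], flank: int = 50) -> list[TargetWindow]:
    """Reference/edited windows in transcript (sense) orientation, one per
    transcript whose 3'UTR contains the site; truncated at transcript ends."""
    out = []
    for tx in gene.transcripts:
        if not any(iv.contains(pos) for iv in tx.utr3):
            continue
        t = transcript_coord(tx, pos)
        if t is None:
            continue
        seq = spliced_sequence(tx, genome)
        sense_ref = ref if tx.strand != "-" else revcomp(ref)
        sense_alt = alt if tx.strand != "-" else revcomp(alt)
        if seq[t] != sense_ref:
            raise ValueError(f"{site_id}: transcript base {seq[t]} != ref {sense_ref}")
        lo = max(0, t - flank)
        hi = min(len(seq), t + flank + 1)
        ref_w = seq[lo:hi]
        center = t - lo
        edit_w = ref_w[:center] + sense_alt + ref_w[center + 1:]
        out.append(TargetWindow(site_id=site_id, transcript_id=tx.transcript_id,
                                ref_seq=ref_w, edited_seq=edit_w, center=center))
    return out


def _best_hits(windows: list[str], mirnas: dict[str, str],
               params: DuplexParams) -> dict[str, DuplexHit]:
    """Best hit per miRNA across windows (max score, then min deltaG)."""
    best: dict[str, DuplexHit] = {}
    for win in windows:
        for name, seq in mirnas.items():
            hit = score_duplex(seq, win, params, mirna_name=name)
            if hit is None:
                continue
            cur = best.get(name)
            if cur is None or (hit.score, -hit.dg) > (cur.score, -cur.dg):
                best[name] = hit
    return best


def classify_regulation_change(site_id: str, ref_hits: dict[str, DuplexHit],
                               edited_hits: dict[str, DuplexHit],
                               ddg_threshold: float = 14.0,
                               ) -> list[RegulationChange]:
    """Per-miRNA comparison of reference vs edited hits."""
    out = []
    for name in sorted(set(ref_hits) | set(edited_hits)):
        in_ref, in_edit = name in ref_hits, name in edited_hits
        if in_ref and not in_edit:
            out.append(RegulationChange(site_id, name, "edited_loss"))
        elif in_edit and not in_ref:
            out.append(RegulationChange(site_id, name, "edited_gain"))
        else:
            ddg = edited_hits[name].dg - ref_hits[name].dg
            if abs(ddg) > ddg_threshold:
                out.append(RegulationChange(site_id, name, "edited_change", ddg))
    return out


def call_mirna_consequence(changes: list[RegulationChange],
                           min_changes: int = 10) -> bool:
    """True iff the edit induces more than ``min_changes`` distinct
    miRNA-target regulation changes (gains + losses + changes pooled)."""
    return len({(c.mirna, c.kind) for c in changes}) > min_changes


def rewire_sites(sites: pd.DataFrame, annotations: pd.DataFrame,
                 genes: list[GeneModel], genome: dict[str, str],
                 mirnas: dict[str, str],
                 params: DuplexParams = DuplexParams(),
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the rewiring analysis over all annotated 3'UTR sites.

    Returns (per-pair change table, per-site consequence table).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    change_rows, cons_rows = [], []
    utr3 = annotations[annotations["feature"] == "3UTR"]
    for sid in utr3.index:
        row = sites.loc[sid]
        gene = gene_by_id.get(utr3.loc[sid, "gene_id"])
        if gene is None:
            continue
        windows = build_windows(sid, int(row["pos"]), row["ref"], row["alt"],
                                gene, genome, params.flank)
        if not windows:
            continue
        ref_hits = _best_hits([w.ref_seq for w in windows], mirnas, params)
        edited_hits = _best_hits([w.edited_seq for w in windows], mirnas, params)
        changes = classify_regulation_change(sid, ref_hits, edited_hits,
                                             params.ddg_threshold)
        for c in changes:
            change_rows.append((c.site_id, c.mirna, c.kind, c.ddg))
        cons_rows.append((sid, len(changes), call_mirna_consequence(changes)))
    changes_df = pd.DataFrame(change_rows,
                              columns=["site_id", "mirna", "kind", "ddg"])
    cons_df = pd.DataFrame(cons_rows, columns=["site_id", "n_changes",
                                               "mirna_consequence"]
                           ).set_index("site_id")
    return changes_df, cons_df
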