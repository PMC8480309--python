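"""Motif and gene-set enrichment machinery.

Four pieces:

* MEME minimal-format position weight matrices (PWMs) with log-odds scoring
  against a 0-order background;
* single-strand PWM scanning with *exact* per-position p-values, computed by
  dynamic programming over an integerized score lattice (the null is the
  0-order background over all windows) and Benjamini-Hochberg adjustment
  over every scanned position — mirroring FIMO-style scanning of transcript
  regions (sense strand only; the inputs are mRNA-derived sequences);
* one-tailed Fisher (hypergeometric) enrichment of gene sets, used for motif
  and GO term enrichment against a custom background;
* a deterministic exhaustive k-mer ranking as a simplified discovery
  routine: every k-mer present in the target set is Fisher-tested for
  gene-level over-representation against the background set, with expected
  presence under a first-order (dinucleotide) Markov background reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_model import SequenceSet
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_LUT = {c: i for i, c in enumerate(ALPHABET)}


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T}.

    ``probs`` has shape (w, 4): one probability row per motif position.
    ``background`` is the 0-order nucleotide frequency vector used for
    log-odds scoring and for the exact null distribution.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (w, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(w, 4) log2-odds matrix with the pseudocount folded in."""
        pc = self.pseudocount
        p = (self.probs + pc) / (1.0 + 4.0 * pc)
        return np.log2(p / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.probs.argmax(axis=1))


def pwm_from_consensus(seq: str, motif_id: str | None = None,
                       match_prob: float = 0.997,
                       background: Sequence[float] | None = None) -> PWM:
    """Near-deterministic PWM for a consensus sequence (DNA alphabet)."""
    seq = seq.upper().replace("U", "T")
    w = len(seq)
    probs = np.full((w, 4), (1.0 - match_prob) / 3.0)
    for i, c in enumerate(seq):
        probs[i, _LUT[c]] = match_prob
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(motif_id=motif_id or seq, probs=probs, background=bg)


def load_meme_pwm(path, background: Sequence[float] | None = None) -> list[PWM]:
    """Read PWMs from MEME minimal motif text format.

    The file's ``Background letter frequencies`` line is used unless
    ``background`` overrides it.  A pseudocount of 1e-6 is folded into the
    log-odds scores at scan time.  A probability row not summing to ~1 is a
    hard error.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    bg = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            bg = np.array([freq.get(c, 0.25) for c in ALPHABET])
            bg = bg / bg.sum()
        elif ln.startswith("MOTIF"):
            motif_id = ln.split()[1]
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id!r}: no probability matrix")
            rows = []
            i += 1
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) == 4:
                    try:
                        row = [float(t) for t in toks]
                    except ValueError:
                        break
                    if abs(sum(row) - 1.0) > 1e-3:
                        raise ValueError(
                            f"motif {motif_id!r}: probability row {row} "
                            f"does not sum to 1")
                    rows.append(row)
                    i += 1
                else:
                    break
            if not rows:
                raise ValueError(f"motif {motif_id!r}: empty probability matrix")
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)  # exact renorm
            pwms.append(PWM(motif_id=motif_id, probs=probs,
                            background=(np.asarray(background, float)
                                        if background is not None else bg.copy())))
            continue
        i += 1
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


def write_meme_pwm(pwms: Sequence[PWM], path) -> None:
    """Write PWMs in MEME minimal motif text format."""
    if not pwms:
        raise ValueError("no motifs to write")
    bg = pwms[0].background
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {bg[j]:.6f}" for j, c in enumerate(ALPHABET)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Exact scan p-values
# ---------------------------------------------------------------------------

def score_distribution(pwm: PWM, granularity: float = 1e-3):
    """Exact null distribution of the integerized window score.

    Scores are rounded to multiples of ``granularity`` bits; the
    distribution of the total over a random background window is the
    convolution of the per-position distributions.  Returns
    (int_scores (w,4), offset, tail) where ``tail[s - offset]`` =
    Pr(total integer score >= s).
    """
    lo = pwm.log_odds()
    ints = np.rint(lo / granularity).astype(np.int64)
    mins = ints.min(axis=1)
    cur = np.array([1.0])
    for i in range(pwm.width):
        span = int(ints[i].max() - mins[i])
        new = np.zeros(cur.size + span)
        for j in range(4):
            sh = int(ints[i, j] - mins[i])
            new[sh:sh + cur.size] += pwm.background[j] * cur
        cur = new
    offset = int(mins.sum())
    tail = np.cumsum(cur[::-1])[::-1]
    return ints, offset, tail


@dataclass
class MotifHit:
    gene: str
    region: str
    start: int          # 1-based, inclusive
    matched: str
    score: float        # log2-odds, bits
    p_raw: float
    p_adj: float


def pwm_scan(pwm: PWM, seqs: SequenceSet, region: str,
             alpha_raw: float = 1e-4, alpha_adj: float | None = 1e-3,
             granularity: float = 1e-3, adjust: str = "bh") -> list[MotifHit]:
    """Scan one region of every gene with a PWM (sense strand only).

    Every window position gets an exact p-value Pr(score >= s) under the
    0-order background; adjusted p-values (BH by default, Bonferroni with
    ``adjust='bonferroni'``) are computed over *all* scanned positions of
    the run.  A position is reported iff p_raw < ``alpha_raw`` and
    p_adj < ``alpha_adj``.

    ``alpha_adj=None`` disables the adjusted gate (hits on raw p only):
    appropriate for *matched-sequence identification* with a short
    consensus motif, whose smallest attainable p-value — the background
    probability of the consensus word, ~2e-5 for an 8-mer — cannot clear a
    strict FDR threshold over a many-thousand-position scan no matter how
    real the motif is.  The adjusted gate is meant for specificity scans
    with wide, information-rich matrices.
    """
    w = pwm.width
    ints, offset, tail = score_distribution(pwm, granularity)
    hi = offset + tail.size - 1

    genes, starts, scores_int, windows = [], [], [], []
    n_scannable = 0
    for gene in seqs.gene_ids:
        s = seqs.region(gene, region)
        if len(s) < w:
            continue
        n_scannable += 1
        try:
            enc = np.array([_LUT[c] for c in s], dtype=np.int64)
        except KeyError:
            # windows containing ambiguity codes are skipped below
            enc = np.array([_LUT.get(c, -1) for c in s], dtype=np.int64)
        for start in range(len(s) - w + 1):
            win = enc[start:start + w]
            if (win < 0).any():
                continue
            genes.append(gene)
            starts.append(start)
            scores_int.append(int(ints[np.arange(w), win].sum()))
            windows.append(s[start:start + w])
    if n_scannable == 0:
        raise ValueError(f"no gene has a {region} sequence of length >= {w}")
    if not genes:
        return []
    si = np.asarray(scores_int)
    p_raw = tail[np.clip(si - offset, 0, tail.size - 1)]
    p_raw = np.where(si > hi, 0.0, p_raw)
    p_raw = np.where(si < offset, 1.0, p_raw)
    if adjust == "bh":
        p_adj = bh_adjust(p_raw)
    elif adjust == "bonferroni":
        p_adj = np.minimum(p_raw * p_raw.size, 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    hits = []
    keep = p_raw < alpha_raw
    if alpha_adj is not None:
        keep &= p_adj < alpha_adj
    for k in np.nonzero(keep)[0]:
        hits.append(MotifHit(gene=genes[k], region=region, start=starts[k] + 1,
                             matched=windows[k], score=float(si[k] * granularity),
                             p_raw=float(p_raw[k]), p_adj=float(p_adj[k])))
    return hits


def hits_frame(hits: Sequence[MotifHit], motif_id: str) -> pd.DataFrame:
    """FIMO-like hit table (motif_id, sequence_name, start, stop, score, ...)."""
    return pd.DataFrame([{
        "motif_id": motif_id, "sequence_name": h.gene, "region": h.region,
        "start": h.start, "stop": h.start + len(h.matched) - 1,
        "score": h.score, "p-value": h.p_raw, "q-value": h.p_adj,
        "matched_sequence": h.matched,
    } for h in hits])


def motif_gene_sets(hits: Iterable[MotifHit]) -> dict[str, list[str]]:
    """Deduplicated gene membership per region (genes counted once,
    regardless of how many sites they contain)."""
    out: dict[str, set] = {}
    for h in hits:
        out.setdefault(h.region, set()).add(h.gene)
    return {region: sorted(genes) for region, genes in out.items()}


# ---------------------------------------------------------------------------
# Fisher / hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term: str
    a: int  # set & annotated
    b: int  # set & not annotated
    c: int  # (background \ set) & annotated
    d: int  # (background \ set) & not annotated
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    zero_corrected: bool = False

    def as_dict(self) -> dict:
        return dict(term=self.term, a=self.a, b=self.b, c=self.c, d=self.d,
                    odds_ratio=self.odds_ratio, p=self.p, p_adj=self.p_adj,
                    zero_corrected=self.zero_corrected)


def _fisher_one_tailed(a: int, b: int, c: int, d: int,
                       alternative: str = "greater") -> float:
    """Exact hypergeometric tail of a 2x2 table."""
    N = a + b + c + d
    K = a + c          # annotated in population
    n = a + b          # set size
    if alternative == "greater":
        return float(hypergeom.sf(a - 1, N, K, n))
    if alternative == "less":
        return float(hypergeom.cdf(a, N, K, n))
    raise ValueError("alternative must be 'greater' or 'less'")


def fisher_enrichment(set_genes: Iterable[str], background_genes: Iterable[str],
                      annotated_genes: Iterable[str], term: str = "",
                      alternative: str = "greater") -> EnrichmentResult:
    """One-tailed Fisher's exact test of annotation enrichment in a gene set.

    The 2x2 table is (set vs background-without-set) x (annotated vs not);
    the set must be a subset of the background and the annotated genes must
    lie inside the background.  The odds ratio is (a*d)/(b*c) with a 0.5
    Haldane correction when any cell is zero (flagged).
    """
    set_g = set(set_genes)
    bg_g = set(background_genes)
    ann_g = set(annotated_genes)
    if not set_g <= bg_g:
        raise ValueError("gene set must be a subset of the background")
    if not ann_g <= bg_g:
        raise ValueError("annotated genes must be a subset of the background")
    rest = bg_g - set_g
    a = len(set_g & ann_g)
    b = len(set_g) - a
    c = len(rest & ann_g)
    d = len(rest) - c
    p = _fisher_one_tailed(a, b, c, d, alternative)
    zero = 0 in (a, b, c, d)
    if zero:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(term=term, a=a, b=b, c=c, d=d,
                            odds_ratio=float(orr), p=p, zero_corrected=zero)


def go_enrichment(set_genes: Iterable[str], background_genes: Iterable[str],
                  ann, alpha: float = 0.05) -> pd.DataFrame:
    """Flat GO-term enrichment of a gene set against a custom background.

    Each term annotating at least one set gene gets a one-tailed
    hypergeometric p; BH adjustment runs over the tested terms; terms are
    significant at adjusted p < ``alpha``.  No GO-graph propagation: term
    sets are used exactly as annotated.
    """
    set_g = list(dict.fromkeys(set_genes))
    bg_g = set(background_genes)
    term_genes: dict[str, set] = {}
    for g in bg_g:
        for t in ann.go_terms.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    if not term_genes:
        raise ValueError("no GO annotation covers the background")
    set_s = set(set_g)
    results = []
    for t in sorted(term_genes):
        if not (term_genes[t] & set_s):
            continue
        results.append(fisher_enrichment(set_s, bg_g, term_genes[t], term=t))
    if not results:
        return pd.DataFrame(columns=["term", "a", "b", "c", "d", "odds_ratio",
                                     "p", "p_adj", "zero_corrected", "significant"])
    padj = bh_adjust([r.p for r in results])
    for r, q in zip(results, padj):
        r.p_adj = float(q)
    df = pd.DataFrame([r.as_dict() for r in results])
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values(["p_adj", "p", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Exhaustive k-mer ranking (simplified deterministic discovery)
# ---------------------------------------------------------------------------

def _gene_kmer_presence(seqs: Mapping[str, str], k: int) -> dict[str, set]:
    pres: dict[str, set] = {}
    for gene, s in seqs.items():
        if len(s) < k:
            continue
        pres[gene] = {s[i:i + k] for i in range(len(s) - k + 1)}
    return pres


def _dinucleotide_model(seqs: Iterable[str]):
    """First-order Markov model (initial + transition) of a sequence group."""
    init = np.full(4, 1.0)  # +1 smoothing
    trans = np.full((4, 4), 1.0)
    for s in seqs:
        enc = [_LUT[c] for c in s if c in _LUT]
        if not enc:
            continue
        init[enc[0]] += 1
        for x, y in zip(enc[:-1], enc[1:]):
            trans[x, y] += 1
    init = init / init.sum()
    trans = trans / trans.sum(axis=1, keepdims=True)
    return init, trans


def _markov_prob(kmer: str, init: np.ndarray, trans: np.ndarray) -> float:
    enc = [_LUT[c] for c in kmer]
    p = init[enc[0]]
    for x, y in zip(enc[:-1], enc[1:]):
        p *= trans[x, y]
    return float(p)


def kmer_discovery(target_seqs: Mapping[str, str] | Sequence[str],
                   background_seqs: Mapping[str, str] | Sequence[str],
                   k_range: Iterable[int] = range(5, 9),
                   top_n: int = 25) -> pd.DataFrame:
    """Rank k-mers over-represented in target genes vs background genes.

    For every k-mer present in at least one target sequence, gene-level
    presence is Fisher-tested (one-tailed, targets vs background) and BH
    adjusted across all tested k-mers.  Expected per-gene presence under a
    first-order Markov (dinucleotide) model of the background group is
    reported for reference.  Fully deterministic — this is an exhaustive
    enumeration, not an EM motif model.
    """
    if not isinstance(target_seqs, Mapping):
        target_seqs = {f"t{i}": s for i, s in enumerate(target_seqs)}
    if not isinstance(background_seqs, Mapping):
        background_seqs = {f"b{i}": s for i, s in enumerate(background_seqs)}
    if not target_seqs or not background_seqs:
        raise ValueError("both sequence groups must be non-empty")
    n_t = len(target_seqs)
    n_b = len(background_seqs)
    min_len = min(len(s) for s in target_seqs.values())
    init, trans = _dinucleotide_model(background_seqs.values())
    bg_lens = np.array([len(s) for s in background_seqs.values()])

    rows = []
    any_k = False
    for k in sorted(set(int(k) for k in k_range)):
        if k > min_len:
            log.info("kmer_discovery: k=%d exceeds shortest target (%d nt); skipped",
                     k, min_len)
            continue
        any_k = True
        tpres = _gene_kmer_presence(target_seqs, k)
        bpres = _gene_kmer_presence(background_seqs, k)
        tcount: dict[str, int] = {}
        for kmers in tpres.values():
            for km in kmers:
                tcount[km] = tcount.get(km, 0) + 1
        bcount: dict[str, int] = {}
        for kmers in bpres.values():
            for km in kmers:
                if km in tcount:
                    bcount[km] = bcount.get(km, 0) + 1
        kmers = sorted(tcount)
        a = np.array([tcount[km] for km in kmers])
        c = np.array([bcount.get(km, 0) for km in kmers])
        p = hypergeom.sf(a - 1, n_t + n_b, a + c, n_t)
        for km, ai, ci, pi in zip(kmers, a, c, p):
            pk = _markov_prob(km, init, trans)
            exp_pres = float(np.mean(1.0 - (1.0 - pk) ** np.maximum(bg_lens - k + 1, 0)))
            rows.append({"kmer": km, "k": k, "n_target": int(ai),
                         "n_background": int(ci), "p": float(pi),
                         "expected_presence": exp_pres})
    if not any_k:
        raise ValueError("every requested k exceeds the shortest target sequence")
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p_adj", "p", "kmer"], kind="stable").reset_index(drop=True)
    return df.head(top_n) if top_n else df
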