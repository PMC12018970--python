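"""Corpus-level caption evaluation: BLEU, ROUGE, CIDEr-D, SPICE contract, Sm.

Conventions follow the standard captioning toolchain:

* **BLEU-1..4** — corpus-level modified n-gram precision with brevity
  penalty, geometric mean up to each order, no smoothing.
* **ROUGE-1/2/L** — per-image maximum over references of the F-measure
  (beta = 1.2) on n-gram overlap (1, 2) or longest common subsequence (L),
  averaged over the corpus.
* **CIDEr-D** — TF-IDF-weighted n-gram cosine consensus for n = 1..4 with
  count clipping and a Gaussian length penalty (sigma = 6), averaged over
  n and scaled by 10, so scores live in [0, 10].
* **SPICE** — a plug-in contract: any callable mapping (hypotheses,
  references) to a score in [0, 1].  Scene-graph parsing is external to
  this package; :func:`naive_spice` is a deliberately simple word-pair F1
  stand-in for fixture tests and is NOT the real SPICE metric.
* **Sm** — the weighted aggregate
  ``(1/7) * BLEU4 + (2/7) * (ROUGE_L + SPICE + CIDEr)``; undefined
  without a SPICE score.

Reported scores are rounded to 3 decimals.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .dataset_io import tokenize

__all__ = [
    "ScoreReport",
    "bleu_n",
    "rouge_scores",
    "cider",
    "sm_score",
    "naive_spice",
    "evaluate",
]

logger = logging.getLogger(__name__)

_ROUGE_BETA = 1.2
_CIDER_SIGMA = 6.0
_CIDER_N = 4

SpicePlugin = Callable[[Sequence[str], Sequence[Sequence[str]]], float]


@dataclass
class ScoreReport:
    """Per-metric corpus scores, rounded to 3 decimals."""

    bleu: tuple[float, float, float, float]
    rouge1: float
    rouge2: float
    rougeL: float
    cider: float
    spice: Optional[float] = None
    sm: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "bleu1": self.bleu[0],
            "bleu2": self.bleu[1],
            "bleu3": self.bleu[2],
            "bleu4": self.bleu[3],
            "rouge1": self.rouge1,
            "rouge2": self.rouge2,
            "rougeL": self.rougeL,
            "cider": self.cider,
        }
        if self.spice is not None:
            d["spice"] = self.spice
        if self.sm is not None:
            d["sm"] = self.sm
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _check_corpora(hypotheses, references) -> None:
    if not hypotheses:
        raise ValueError("empty hypothesis corpus")
    if len(hypotheses) != len(references):
        raise ValueError(f"{len(hypotheses)} hypotheses vs {len(references)} reference sets")
    if any(not refs for refs in references):
        raise ValueError("every item needs at least one reference")


# -- BLEU ----------------------------------------------------------------------


def bleu_n(
    hypotheses: Sequence[str],
    references: Sequence[Sequence[str]],
    max_n: int = 4,
) -> tuple[float, ...]:
    """Corpus BLEU-1..max_n: clipped precision, brevity penalty, geometric mean."""
    _check_corpora(hypotheses, references)
    matched = [0] * max_n
    total = [0] * max_n
    hyp_len = 0
    ref_len = 0
    for hyp, refs in zip(hypotheses, references):
        h = tokenize(hyp)
        rs = [tokenize(r) for r in refs]
        hyp_len += len(h)
        # closest reference length (ties -> shorter)
        ref_len += min((abs(len(r) - len(h)), len(r)) for r in rs)[1]
        for n in range(1, max_n + 1):
            hc = _ngrams(h, n)
            clip = Counter()
            for r in rs:
                rc = _ngrams(r, n)
                for g, c in hc.items():
                    clip[g] = max(clip[g], min(c, rc[g]))
            matched[n - 1] += sum(clip.values())
            total[n - 1] += max(0, len(h) - n + 1)
    bp = 1.0 if hyp_len > ref_len else math.exp(1.0 - ref_len / max(hyp_len, 1))
    scores = []
    for k in range(1, max_n + 1):
        precs = [matched[n] / total[n] if total[n] else 0.0 for n in range(k)]
        if min(precs) <= 0:
            scores.append(0.0)
        else:
            scores.append(bp * math.exp(sum(math.log(p) for p in precs) / k))
    return tuple(scores)


# -- ROUGE ---------------------------------------------------------------------


def _fbeta(p: float, r: float, beta: float = _ROUGE_BETA) -> float:
    if p <= 0 or r <= 0:
        return 0.0
    return (1 + beta**2) * p * r / (r + beta**2 * p)


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    """Dynamic-programming longest common subsequence length."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_scores(
    hypotheses: Sequence[str], references: Sequence[Sequence[str]]
) -> tuple[float, float, float]:
    """(ROUGE-1, ROUGE-2, ROUGE-L): per-item max over references, corpus mean."""
    _check_corpora(hypotheses, references)
    sums = [0.0, 0.0, 0.0]
    for hyp, refs in zip(hypotheses, references):
        h = tokenize(hyp)
        rs = [tokenize(r) for r in refs]
        for idx, n in enumerate((1, 2)):
            hc = _ngrams(h, n)
            best = 0.0
            for r in rs:
                rc = _ngrams(r, n)
                overlap = sum((hc & rc).values())
                p = overlap / max(sum(hc.values()), 1)
                rec = overlap / max(sum(rc.values()), 1)
                best = max(best, _fbeta(p, rec))
            sums[idx] += best
        best_l = 0.0
        for r in rs:
            lcs = _lcs_len(h, r)
            p = lcs / len(h) if h else 0.0
            rec = lcs / len(r) if r else 0.0
            best_l = max(best_l, _fbeta(p, rec))
        sums[2] += best_l
    n_items = len(hypotheses)
    return sums[0] / n_items, sums[1] / n_items, sums[2] / n_items


# -- CIDEr-D -------------------------------------------------------------------


def _cider_vec(counts: Counter, doc_freq: Counter, log_n: float):
    vec = [dict() for _ in range(_CIDER_N)]
    norm = [0.0] * _CIDER_N
    length = 0
    for ngram, tf in counts.items():
        idf = log_n - math.log(max(1.0, doc_freq[ngram]))
        k = len(ngram) - 1
        vec[k][ngram] = tf * idf
        norm[k] += vec[k][ngram] ** 2
        if k == 0:
            length += tf
    return vec, [math.sqrt(x) for x in norm], length


def cider(hypotheses: Sequence[str], references: Sequence[Sequence[str]]) -> float:
    """CIDEr-D corpus score in [0, 10]."""
    _check_corpora(hypotheses, references)
    if len(hypotheses) < 2:
        logger.warning("CIDEr on a single-image corpus: IDF is degenerate")
    def all_counts(toks: Sequence[str]) -> Counter:
        c: Counter = Counter()
        for n in range(1, _CIDER_N + 1):
            c.update(_ngrams(toks, n))
        return c
    ref_counts = [[all_counts(tokenize(r)) for r in refs] for refs in references]
    doc_freq: Counter = Counter()
    for refs in ref_counts:
        seen = set()
        for rc in refs:
            seen.update(rc)
        doc_freq.update(seen)
    log_n = math.log(max(float(len(references)), 1.0))
    total = 0.0
    for hyp, refs in zip(hypotheses, ref_counts):
        hv, hnorm, hlen = _cider_vec(all_counts(tokenize(hyp)), doc_freq, log_n)
        item = [0.0] * _CIDER_N
        for rc in refs:
            rv, rnorm, rlen = _cider_vec(rc, doc_freq, log_n)
            penalty = math.exp(-((hlen - rlen) ** 2) / (2 * _CIDER_SIGMA**2))
            for k in range(_CIDER_N):
                dot = sum(min(w, rv[k].get(g, 0.0)) * rv[k].get(g, 0.0) for g, w in hv[k].items())
                if hnorm[k] and rnorm[k]:
                    dot /= hnorm[k] * rnorm[k]
                item[k] += dot * penalty
        total += sum(item) / _CIDER_N / len(refs)
    return 10.0 * total / len(hypotheses)


# -- SPICE contract ------------------------------------------------------------


def naive_spice(hypotheses: Sequence[str], references: Sequence[Sequence[str]]) -> float:
    """Word-pair F1 stand-in for SPICE — synthetic-fixture testing only.

    Extracts (attribute, object) propositions as adjacent token pairs plus
    bare tokens, scores hypothesis sets against the union of reference sets
    by F1, and averages.  This is a position-heuristic toy, not the
    real scene-graph metric, and is labelled as such wherever used.
    """
    _check_corpora(hypotheses, references)

    def props(text: str) -> set:
        toks = tokenize(text)
        return set(toks) | set(zip(toks, toks[1:]))

    total = 0.0
    for hyp, refs in zip(hypotheses, references):
        hp = props(hyp)
        rp = set().union(*(props(r) for r in refs))
        overlap = len(hp & rp)
        p = overlap / len(hp) if hp else 0.0
        r = overlap / len(rp) if rp else 0.0
        total += 2 * p * r / (p + r) if p + r else 0.0
    return total / len(hypotheses)


# -- Sm ------------------------------------------------------------------------


def sm_score(bleu4: float, rougeL: float, spice: float, cider_score: float) -> float:
    """Weighted aggregate: (1/7) BLEU-4 + (2/7) (ROUGE-L + SPICE + CIDEr)."""
    parts = (bleu4, rougeL, spice, cider_score)
    if any(v is None or not math.isfinite(v) for v in parts):
        raise ValueError(f"Sm needs all four finite components, got {parts}")
    return bleu4 / 7.0 + 2.0 / 7.0 * (rougeL + spice + cider_score)


# -- assembly ------------------------------------------------------------------


def evaluate(
    hypotheses: Sequence[str],
    references: Sequence[Sequence[str]],
    spice_plugin: Optional[SpicePlugin] = None,
) -> ScoreReport:
    """Compute every metric; SPICE and Sm appear only when a plug-in is given."""
    _check_corpora(hypotheses, references)
    bleu = tuple(round(b, 3) for b in bleu_n(hypotheses, references))
    r1, r2, rl = (round(x, 3) for x in rouge_scores(hypotheses, references))
    cd = round(cider(hypotheses, references), 3)
    spice = sm = None
    if spice_plugin is not None:
        try:
            spice = round(float(spice_plugin(hypotheses, references)), 3)
            sm = round(sm_score(bleu[3], rl, spice, cd), 3)
        except Exception:  # noqa: BLE001 - plug-in is third-party code
            logger.exception("SPICE plug-in failed; report omits spice and sm")
            spice = sm = None
    return ScoreReport(bleu=bleu, rouge1=r1, rouge2=r2, rougeL=rl, cider=cd, spice=spice, sm=sm)
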