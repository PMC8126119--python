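"""Transparent translation score from periodicity and coverage homogeneity.

Actively translated ORFs show three-nucleotide periodicity (an excess of
P-sites in the ORF's own frame, f1) and spread of the in-frame signal along
the ORF rather than a single pile-up.  The score combines

* a periodicity component ``p* = max(0, (f1_fraction - 1/3) / (2/3))``,
  rescaling the f1 fraction from its chance level (1/3) to [0, 1], and
* the percentage of maximum entropy (PME) of in-frame per-codon coverage,
  ``H / Hmax`` with Shannon entropy in any base (the base cancels),

as ``score = sqrt(p* x PME)``, a geometric mean in [0, 1].  The score is 1
only for fully in-frame, perfectly even coverage, and 0 whenever the f1
fraction is at or below chance.  uORFs are called translated when the pooled
read count across all samples reaches ``min_reads`` and the score exceeds
the threshold (strict inequality, default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .read_counting import FootprintProfile

NO_SIGNAL = "no_signal"


@dataclass
class TranslationScore:
    uorf_id: str
    f1_fraction: float
    pme: float | str  # NO_SIGNAL when there are no in-frame reads
    score: float
    n_reads: int


def compute_pme(codon_counts: np.ndarray) -> float | str:
    """Entropy of in-frame coverage relative to uniform, in [0, 1].

    Returns :data:`NO_SIGNAL` when there are no in-frame reads; 0.0 when all
    reads sit on a single codon; 1.0 for perfectly uniform coverage.
    """
    counts = np.asarray(codon_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("PME needs at least 2 codon positions")
    total = counts.sum()
    if total == 0:
        return NO_SIGNAL
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(counts.size)


def translation_score(profile: FootprintProfile) -> TranslationScore:
    """Score one uORF profile; 0 without periodicity or in-frame signal."""
    f1, f2, f3 = profile.frame_counts
    n = f1 + f2 + f3
    if n == 0:
        return TranslationScore(profile.uorf_id, 0.0, NO_SIGNAL, 0.0, 0)
    f1_frac = f1 / n
    pme = compute_pme(profile.codon_counts)
    p_star = max(0.0, (f1_frac - 1 / 3) / (2 / 3))
    score = 0.0 if pme == NO_SIGNAL else float(np.sqrt(p_star * pme))
    return TranslationScore(profile.uorf_id, f1_frac, pme, score, n)


def pooled_scores(
    profiles_by_sample: dict[tuple[str, str], FootprintProfile]
) -> pd.DataFrame:
    """Pool profiles across samples per uORF and score the pooled profile.

    Selection in the analysis uses counts "considering all samples
    together", so frame counts and codon coverage are summed over samples
    before scoring.
    """
    pooled: dict[str, FootprintProfile] = {}
    for (uorf_id, _sample), prof in profiles_by_sample.items():
        if uorf_id not in pooled:
            pooled[uorf_id] = FootprintProfile(
                uorf_id, prof.codon_counts.copy(), prof.frame_counts
            )
        else:
            acc = pooled[uorf_id]
            pooled[uorf_id] = FootprintProfile(
                uorf_id,
                acc.codon_counts + prof.codon_counts,
                tuple(a + b for a, b in zip(acc.frame_counts, prof.frame_counts)),
            )
    rows = []
    for uorf_id in sorted(pooled):
        s = translation_score(pooled[uorf_id])
        rows.append(
            {
                "uorf_id": uorf_id,
                "n_reads": s.n_reads,
                "f1": pooled[uorf_id].frame_counts[0],
                "f2": pooled[uorf_id].frame_counts[1],
                "f3": pooled[uorf_id].frame_counts[2],
                "f1_fraction": s.f1_fraction,
                "pme": np.nan if s.pme == NO_SIGNAL else s.pme,
                "score": s.score,
            }
        )
    return pd.DataFrame(rows).set_index("uorf_id")


def select_translated(
    scores: pd.DataFrame,
    n_codons: "pd.Series | dict[str, int]",
    threshold: float = 0.7,
    min_reads: int = 10,
    min_codons: int = 10,
) -> set[str]:
    """Bona fide translated uORFs: pooled reads >= ``min_reads``, score
    strictly above ``threshold`` and length >= ``min_codons`` codons."""
    ncod = pd.Series(n_codons)
    out = set()
    for uorf_id, row in scores.iterrows():
        if (
            row["n_reads"] >= min_reads
            and row["score"] > threshold
            and ncod.get(uorf_id, 0) >= min_codons
        ):
            out.add(uorf_id)
    return out
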