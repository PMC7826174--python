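"""PWM scanning and allele-dependent motif gain/loss calls.

Windows are scored with the log-likelihood ratio sum(log(p_base/bg_base))
and min-max rescaled to a relative profile score in [0, 1]; hits are windows
on either strand with relative score >= the threshold (default 0.95, the
JASPAR convention).  Zero probabilities are floored with a small epsilon
before taking logs so minimum and maximum scores stay finite; the consensus
window still scores exactly 1 and the per-column-minimum window exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import PWM

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PROB_EPSILON = 1e-4


@dataclass
class MotifHit:
    matrix_id: str
    offset: int  # 0-based offset on the forward sequence
    strand: str  # "+" or "-"
    relative_score: float


def _log_odds(pwm: PWM) -> np.ndarray:
    probs = (pwm.probabilities + PROB_EPSILON) / (1.0 + 4 * PROB_EPSILON)
    bg = pwm.background / pwm.background.sum()
    return np.log(probs / bg[:, None])


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8)
            == ord(base)] = idx
    return out


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(COMPLEMENT)[::-1]


def pwm_relative_scores(sequence: str, pwm: PWM,
                        threshold: float = 0.95) -> list:
    """Motif hits over both strands of ``sequence``.

    Windows containing a non-ACGT character are skipped.  Reverse-strand
    hits are reported at the forward-sequence offset of the window they
    cover, so a hit at (offset, strand "-") spans the same positions as a
    forward hit at that offset.
    """
    lom = _log_odds(pwm)
    L = pwm.length
    smin = lom.min(axis=0).sum()
    smax = lom.max(axis=0).sum()
    span = smax - smin
    enc_fwd = _encode(sequence)
    n = len(sequence) - L + 1
    hits = []
    if n <= 0:
        return hits
    for strand in "+-":
        if strand == "+":
            enc = enc_fwd
        else:
            enc = _encode(reverse_complement(sequence))
        # windows as a (n, L) view
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (win >= 0).all(axis=1)
        scores = np.full(win.shape[0], -np.inf)
        if valid.any():
            idx = np.clip(win[valid], 0, 3)
            scores[valid] = lom[idx, np.arange(L)[None, :]].sum(axis=1)
        rel = (scores - smin) / span if span > 0 else np.where(
            np.isfinite(scores), 1.0, -np.inf)
        for off in np.nonzero(rel >= threshold)[0]:
            fwd_off = int(off) if strand == "+" else len(sequence) - L - int(off)
            hits.append(MotifHit(pwm.matrix_id, fwd_off, strand,
                                 float(rel[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _best_score(sequence: str, pwm: PWM) -> float:
    """Best relative score over both strands (no threshold)."""
    hits = pwm_relative_scores(sequence, pwm, threshold=-np.inf)
    finite = [h.relative_score for h in hits
              if np.isfinite(h.relative_score)]
    return max(finite) if finite else float("nan")


def build_allele_sequences(reference_sequence: str, variant_pos: int,
                           ref_allele: str, alt_allele: str,
                           flank_bp: int = 20) -> tuple:
    """Reference- and alternate-allele sequences around a variant.

    ``variant_pos`` is the 0-based index of the variant start within
    ``reference_sequence``; ``ref_allele`` is the reference bases at that
    position (one base for a SNP, the deleted span for a deletion with
    alt_allele "").  Returns ``(ref_seq, alt_seq, edit_start, ref_edit_end,
    alt_edit_end)`` where the edit interval is the variant region within
    each returned sequence (half-open, 0-based).
    """
    if reference_sequence[variant_pos:variant_pos + len(ref_allele)] != ref_allele:
        raise ValueError("ref_allele does not match the reference sequence")
    left = reference_sequence[max(0, variant_pos - flank_bp):variant_pos]
    right = reference_sequence[variant_pos + len(ref_allele):
                               variant_pos + len(ref_allele) + flank_bp]
    ref_seq = left + ref_allele + right
    alt_seq = left + alt_allele + right
    start = len(left)
    return (ref_seq, alt_seq, start, start + len(ref_allele),
            start + len(alt_allele))


def _spans_edit(hits: Sequence[MotifHit], length: int, edit_start: int,
                edit_end: int) -> bool:
    """Any hit window overlapping the edited region (junction for len 0)."""
    lo, hi = edit_start, max(edit_end, edit_start)
    for h in hits:
        if lo == hi:
            # empty edit (deletion allele): the window must straddle the
            # junction to be affected
            if h.offset < lo and h.offset + length > lo:
                return True
        elif h.offset < hi and h.offset + length > lo:
            return True
    return False


def allele_motif_comparison(ref_seq: str, alt_seq: str, edit_start: int,
                            ref_edit_end: int, alt_edit_end: int,
                            pwms: Sequence[PWM],
                            threshold: float = 0.95) -> list:
    """Per-PWM motif status between the two allele sequences.

    A motif counts as present on an allele when a hit window spans the
    edited region of that allele's sequence (for a pure deletion allele,
    the deletion junction).  Returns a list of dicts with keys matrix_id,
    name, status ("unchanged", "lost_in_alt", "gained_in_alt"),
    best_score_ref, best_score_alt.
    """
    out = []
    for pwm in pwms:
        ref_hits = pwm_relative_scores(ref_seq, pwm, threshold)
        alt_hits = pwm_relative_scores(alt_seq, pwm, threshold)
        in_ref = _spans_edit(ref_hits, pwm.length, edit_start, ref_edit_end)
        in_alt = _spans_edit(alt_hits, pwm.length, edit_start, alt_edit_end)
        if in_ref and not in_alt:
            status = "lost_in_alt"
        elif in_alt and not in_ref:
            status = "gained_in_alt"
        else:
            status = "unchanged"
        out.append({
            "matrix_id": pwm.matrix_id,
            "name": pwm.name,
            "status": status,
            "best_score_ref": _best_score(ref_seq, pwm),
            "best_score_alt": _best_score(alt_seq, pwm),
        })
    return out
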