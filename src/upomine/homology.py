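"""Pairwise local-alignment homology screen with E-value statistics.

Candidate heme-thiolate peroxidases are pulled out of a proteome by
Smith–Waterman local alignment against a query (an AaeUPO homolog)
under BLOSUM62 with affine gaps, scored with Karlin–Altschul extreme
value statistics: ``E = K · m · n · exp(-λ·S)`` with the database
length n taken as the proteome's summed residue count.  Two-tier
thresholds mirror common profile-search practice: a permissive
reporting E-value (default 10.0) and a strict inclusion E-value
(default 0.01, i.e. roughly one random false positive per hundred
searches).

For the default scheme (BLOSUM62, gap open 11 / extend 1) the gapped
statistical parameters are the community-standard empirical values
(λ = 0.267, K = 0.041, H = 0.14).  For custom ungapped schemes
:func:`calibrate_lambda` solves the Karlin–Altschul identity
``Σ pᵢpⱼ·exp(λ·sᵢⱼ) = 1`` directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.optimize import brentq

from upomine.io_formats import CANONICAL, ProteinRecord

#: Published gapped Karlin–Altschul parameters for (matrix, open, extend).
GAPPED_PARAMS = {
    ("BLOSUM62", 11, 1): (0.267, 0.041, 0.14),
    ("BLOSUM62", 10, 1): (0.243, 0.024, 0.10),
    ("BLOSUM45", 14, 2): (0.195, 0.021, 0.10),
    ("BLOSUM80", 10, 1): (0.277, 0.044, 0.21),
}


class CalibrationError(ValueError):
    """Raised when a scoring scheme admits no Karlin–Altschul λ."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, gap penalties and statistical parameters.

    ``gap_open``/``gap_extend`` are positive penalties; opening a gap of
    length 1 costs ``gap_open + gap_extend``.  ``background`` holds the
    residue frequencies used for λ calibration (uniform by default).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    background: tuple[float, ...] = tuple([1.0 / 20] * 20)
    lambda_: float | None = None
    K: float | None = None
    H: float | None = None
    custom_matrix: object = None  # a substitution_matrices.Array, overrides name

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.lambda_ is not None and self.lambda_ <= 0:
            raise ValueError("lambda must be positive")

    @property
    def matrix(self):
        if self.custom_matrix is not None:
            return self.custom_matrix
        return _load_matrix(self.matrix_name)

    def with_stats(self) -> "ScoringScheme":
        """Return a scheme with λ/K/H resolved (lookup table or analytic λ)."""
        if self.lambda_ is not None and self.K is not None:
            return self
        key = (self.matrix_name, self.gap_open, self.gap_extend)
        if key in GAPPED_PARAMS:
            lam, K, H = GAPPED_PARAMS[key]
            return replace(self, lambda_=lam, K=K, H=H)
        lam = calibrate_lambda(self)
        # Without an empirical K, fall back on a conservative default.
        return replace(self, lambda_=lam, K=self.K if self.K is not None else 0.1,
                       H=self.H if self.H is not None else 0.1)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    Spans are 1-based inclusive ``(start, end)`` on each sequence, or
    ``None`` when the optimal local alignment is empty (score 0).
    ``pct_identity`` is computed over all alignment columns, gap columns
    included.
    """

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int] | None
    subject_span: tuple[int, int] | None
    pct_identity: float


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=scheme.matrix,
        open_gap_score=-(scheme.gap_open + scheme.gap_extend),
        extend_gap_score=-scheme.gap_extend,
    )
    return aligner


def local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Optimal Smith–Waterman score only (no traceback; fast path)."""
    return float(_make_aligner(scheme).score(a, b))


def local_align(
    a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme | None = None
) -> AlignmentHit:
    """Optimal Smith–Waterman alignment of two sequences.

    The local-alignment score floor is 0: sequences with no positively
    scoring residue pair produce a score-0 hit with empty spans.  The
    traceback is deterministic (the aligner's canonical first optimal
    path).  E-value fields are filled by the screening stage; here they
    default to ``inf``/``0`` bit placeholders resolved against m=n=len.
    """
    scheme = (scheme or ScoringScheme()).with_stats()
    aligner = _make_aligner(scheme)
    score = float(aligner.score(a.residues, b.residues))
    if score <= 0:
        return AlignmentHit(a.id, b.id, 0.0, 0.0, math.inf, None, None, 0.0)
    aln = aligner.align(a.residues, b.residues)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    pct = 100.0 * counts.identities / columns if columns else 0.0
    qa, sa = aln.aligned
    q_span = (int(qa[0][0]) + 1, int(qa[-1][1]))
    s_span = (int(sa[0][0]) + 1, int(sa[-1][1]))
    bits = bit_score(score, scheme)
    return AlignmentHit(
        a.id, b.id, score, bits,
        evalue(score, len(a), len(b), scheme),
        q_span, s_span, pct,
    )


def identity_fraction(
    a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme | None = None
) -> float:
    """Identical aligned positions divided by the shorter sequence length.

    The denominator convention of greedy identity clustering (cd-hit).
    """
    scheme = (scheme or ScoringScheme()).with_stats()
    aligner = _make_aligner(scheme)
    if aligner.score(a.residues, b.residues) <= 0:
        return 0.0
    aln = aligner.align(a.residues, b.residues)[0]
    return aln.counts().identities / min(len(a), len(b))


def calibrate_lambda(scheme: ScoringScheme, tol: float = 1e-12) -> float:
    """Solve Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1 for the unique positive root.

    Requires at least one positive score and a negative expected score
    under the background frequencies (otherwise no positive root
    exists and :class:`CalibrationError` is raised).
    """
    m = scheme.matrix
    p = np.asarray(scheme.background)
    # Score array over the scheme's residue alphabet (canonical 20 for
    # the named matrices; a custom matrix brings its own alphabet).
    letters = CANONICAL if scheme.custom_matrix is None else list(m.alphabet)
    if len(p) != len(letters):
        raise ValueError(
            f"background has {len(p)} frequencies for {len(letters)} letters"
        )
    s = np.array([[m[x, y] for y in letters] for x in letters], dtype=float)
    expected = float(p @ s @ p)
    if expected >= 0:
        raise CalibrationError(
            f"expected score {expected:.4f} >= 0; no positive λ exists"
        )
    if s.max() <= 0:
        raise CalibrationError("matrix has no positive entry")

    def f(lam: float) -> float:
        return float(p @ np.exp(lam * s) @ p) - 1.0

    # f(0) = 0, f'(0) = expected < 0, f -> inf: bracket the positive root.
    hi = 1.0 / s.max()
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise CalibrationError("failed to bracket λ")
    lo = hi / 2.0
    while f(lo) > 0:
        lo /= 2.0
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalized score in bits: (λ·S − ln K) / ln 2."""
    scheme = scheme.with_stats()
    return (scheme.lambda_ * raw_score - math.log(scheme.K)) / math.log(2)


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S).

    Linear in both lengths and monotone decreasing in the score.
    """
    scheme = scheme.with_stats()
    return scheme.K * m * n * math.exp(-scheme.lambda_ * raw_score)


def screen_proteome(
    proteome: list[ProteinRecord],
    query: ProteinRecord,
    scheme: ScoringScheme | None = None,
    report_evalue: float = 10.0,
    accept_evalue: float = 0.01,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Screen a proteome against one query sequence.

    Returns ``(accepted, reported)`` hit lists: reported hits satisfy
    ``E <= report_evalue``, accepted hits additionally satisfy the
    inclusion threshold ``E <= accept_evalue``.  Both are ordered by
    E-value then subject id.  The database length for the statistics is
    the summed residue count of the proteome, edge-corrected.
    """
    scheme = (scheme or ScoringScheme()).with_stats()
    if not proteome:
        return [], []
    n_total = sum(len(r) for r in proteome)
    reported: list[AlignmentHit] = []
    for rec in proteome:
        score = local_score(query.residues, rec.residues, scheme)
        if score <= 0:
            continue
        E = evalue(score, len(query), n_total, scheme)
        if E > report_evalue:
            continue
        full = local_align(query, rec, scheme)
        reported.append(replace(full, evalue=E, bit_score=bit_score(score, scheme)))
    reported.sort(key=lambda h: (h.evalue, h.subject_id))
    accepted = [h for h in reported if h.evalue <= accept_evalue]
    return accepted, reported
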