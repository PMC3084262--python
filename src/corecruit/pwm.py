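"""Position weight matrices: validation, log-odds scoring, exact score p-values.

A :class:`PWM` stores per-position base probabilities over the alphabet
``ACGT`` together with a background base distribution.  Scores are log2
odds of the motif model against the background.  The null distribution of
the score of a random background window is computed exactly by dynamic
programming over discretized scores (bin width 0.01 log-odds units), which
gives an exact p-value for any observed score without simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidPWMError

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = 4

#: width of one discretization bin for exact score p-values (log2-odds units)
SCORE_BIN = 0.01


_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as integer codes (A=0 .. T=3, other=N=4)."""
    raw = np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over ACGT with a background distribution.

    Parameters
    ----------
    name : str
        Factor or motif identifier.
    matrix : ndarray, shape (L, 4)
        Per-position base probabilities; every row must sum to 1 within
        1e-9 and every entry must be strictly positive (apply
        :meth:`from_counts` with a pseudocount first if needed).
    background : ndarray, shape (4,)
        Background base probabilities, summing to 1.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise InvalidPWMError(f"{self.name}: matrix must be L x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidPWMError(f"{self.name}: rows must sum to 1")
        if (m <= 0).any():
            raise InvalidPWMError(
                f"{self.name}: zero entries; apply a pseudocount")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9) or (bg <= 0).any():
            raise InvalidPWMError(f"{self.name}: invalid background")

    @classmethod
    def from_counts(cls, name, counts, background=None, pseudocount=0.5):
        """Build a PWM from a count matrix with a pseudocount per cell."""
        counts = np.asarray(counts, dtype=float) + float(pseudocount)
        matrix = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(name, matrix, np.asarray(background, dtype=float))

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log2-odds scores, shape (L, 4)."""
        return np.log2(self.matrix / self.background)

    def reverse_complement(self) -> "PWM":
        """The PWM matching the reverse complement of the motif."""
        return PWM(self.name, self.matrix[::-1, ::-1].copy(), self.background)

    # -- exact p-values ----------------------------------------------------

    def _binned_log_odds(self) -> np.ndarray:
        """Log-odds discretized to integer multiples of SCORE_BIN."""
        return np.rint(self.log_odds() / SCORE_BIN).astype(np.int64)

    def score_distribution(self):
        """Exact null distribution of the discretized window score.

        Returns ``(offset, probs)`` where ``probs[i]`` is the probability
        under the background model that a random window scores
        ``(offset + i) * SCORE_BIN``.
        """
        binned = self._binned_log_odds()
        lo = int(binned.min(axis=1).sum())
        hi = int(binned.max(axis=1).sum())
        probs = np.zeros(hi - lo + 1)
        # start: empty prefix has score 0, stored at index -lo_running
        cur = np.array([1.0])
        cur_lo = 0
        for pos in range(len(self)):
            row = binned[pos]
            new_lo = cur_lo + int(row.min())
            new_hi = cur_lo + len(cur) - 1 + int(row.max())
            new = np.zeros(new_hi - new_lo + 1)
            for base in range(4):
                shift = int(row[base]) - new_lo + cur_lo
                new[shift:shift + len(cur)] += self.background[base] * cur
            cur, cur_lo = new, new_lo
        probs[cur_lo - lo: cur_lo - lo + len(cur)] = cur
        return lo, probs

    def score_pvalues(self):
        """Upper-tail p-value for every attainable discretized score.

        Returns ``(offset, sf)`` where ``sf[i] = P(S >= (offset+i)*SCORE_BIN)``
        under the background model.
        """
        lo, probs = self.score_distribution()
        sf = probs[::-1].cumsum()[::-1]
        return lo, np.minimum(sf, 1.0)

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer-binned score whose exact p-value is < p_threshold.

        Windows scoring at or above the returned value (in SCORE_BIN units)
        are hits at the given threshold.  Returns one past the maximal
        attainable score when no score is significant (no window can hit).
        """
        lo, sf = self.score_pvalues()
        ok = np.nonzero(sf < p_threshold)[0]
        if len(ok) == 0:
            return lo + len(sf)
        return lo + int(ok[0])

    def pvalue_of_score(self, binned_score: int) -> float:
        """Exact p-value of an integer-binned window score."""
        lo, sf = self.score_pvalues()
        idx = int(binned_score) - lo
        if idx < 0:
            return 1.0
        if idx >= len(sf):
            return 0.0
        return float(sf[idx])


def window_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Discretized log-odds score of every window of the encoded sequence.

    Windows containing an ``N`` score ``INT_MIN/4`` sentinel (never a hit).
    Returns an int64 array of length ``len(codes) - len(pwm) + 1`` in
    SCORE_BIN units.
    """
    L = len(pwm)
    n_pos = len(codes) - L + 1
    if n_pos <= 0:
        return np.zeros(0, dtype=np.int64)
    binned = pwm._binned_log_odds()
    # 5th column = large negative sentinel for N
    sentinel = np.iinfo(np.int64).min // (4 * max(L, 1))
    lut = np.concatenate([binned, np.full((L, 1), sentinel, dtype=np.int64)],
                         axis=1)
    scores = np.zeros(n_pos, dtype=np.int64)
    for i in range(L):
        scores += lut[i, codes[i:i + n_pos]]
    return scores
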