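"""Caste comparison of antennal sensitivity (EAG) and FPKM normalization.

Electroantennogram (EAG) recordings measure the summed voltage deflection of a
whole antenna.  Each individual receives one stimulation series —
air, hexane, neocembrene, hexane, air — and its odorant responses are divided
by the mean of its two air (blank) responses, which cancels preparation- and
instrument-gain differences between individuals, then log2-transformed to
reduce heteroscedasticity.  Worker and soldier groups are compared with a
Student's t-test after checking its assumptions (Bartlett's test for equal
variances, Shapiro-Wilk normality per group).

FPKM (Fragments Per Kilobase of transcript per Million mapped fragments)
normalizes raw RNA-seq read counts for transcript length and sequencing depth:
FPKM_g = counts_g * 1e9 / (length_g * library_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EagSeries", "normalize_eag", "caste_test", "fpkm"]

#: Expected stimulus order of one EAG series.
STIMULUS_ORDER = ("air", "hexane", "neocembrene", "hexane", "air")


@dataclass(frozen=True)
class EagSeries:
    """One individual's EAG stimulation series (responses in mV, positive).

    ``responses`` follow :data:`STIMULUS_ORDER`; ``caste`` is ``"worker"`` or
    ``"soldier"``.
    """

    responses: tuple[float, ...]
    caste: str
    individual: str | int = 0

    def __post_init__(self) -> None:
        if len(self.responses) != len(STIMULUS_ORDER):
            raise ValueError(
                f"expected {len(STIMULUS_ORDER)} responses in order "
                f"{STIMULUS_ORDER}")
        if self.caste not in ("worker", "soldier"):
            raise ValueError("caste must be 'worker' or 'soldier'")
        airs = [r for r, s in zip(self.responses, STIMULUS_ORDER) if s == "air"]
        if any(a <= 0 for a in airs):
            raise ValueError("air responses must be > 0 (normalizer)")

    @property
    def air_mean(self) -> float:
        return float(np.mean([r for r, s in zip(self.responses, STIMULUS_ORDER)
                              if s == "air"]))

    def response(self, stimulus: str) -> float:
        """Mean raw response to one stimulus (mean of repeats in the series)."""
        vals = [r for r, s in zip(self.responses, STIMULUS_ORDER)
                if s == stimulus]
        if not vals:
            raise ValueError(f"stimulus {stimulus!r} not in series")
        return float(np.mean(vals))


def normalize_eag(series: EagSeries, stimulus: str = "neocembrene",
                  subtract_hexane: bool = False) -> float:
    """Air-normalized, log2-transformed response of one individual.

    The stimulus response is divided by the mean of the individual's two air
    responses, then log2-transformed.  With ``subtract_hexane`` the mean
    hexane (solvent) response is subtracted from the stimulus response before
    normalization.  Non-positive normalized values cannot be log-transformed
    and are returned as NaN (flagged missing).
    """
    value = series.response(stimulus)
    if subtract_hexane and stimulus != "hexane":
        value = value - series.response("hexane")
    normalized = value / series.air_mean
    if normalized <= 0:
        return float("nan")
    return float(np.log2(normalized))


def caste_test(workers: np.ndarray, soldiers: np.ndarray,
               welch: bool = False) -> dict:
    """Two-sample comparison of normalized EAG responses between castes.

    Reports Bartlett's equal-variance p, per-group Shapiro-Wilk normality p,
    and the Student's t-test (equal variances pooled; ``welch=True`` for the
    unequal-variance variant).  Requires n >= 3 per group and non-degenerate
    variance.
    """
    workers = np.asarray(workers, dtype=float)
    soldiers = np.asarray(soldiers, dtype=float)
    workers = workers[np.isfinite(workers)]
    soldiers = soldiers[np.isfinite(soldiers)]
    if len(workers) < 3 or len(soldiers) < 3:
        raise ValueError("need at least 3 finite values per group")
    if np.var(workers) == 0 and np.var(soldiers) == 0:
        raise ValueError("both groups have zero variance; t-test degenerate")

    bartlett_stat, bartlett_p = stats.bartlett(workers, soldiers)
    sw_w = stats.shapiro(workers)
    sw_s = stats.shapiro(soldiers)
    t = stats.ttest_ind(workers, soldiers, equal_var=not welch)
    return {
        "n_workers": int(len(workers)),
        "n_soldiers": int(len(soldiers)),
        "mean_workers": float(workers.mean()),
        "mean_soldiers": float(soldiers.mean()),
        "bartlett_stat": float(bartlett_stat),
        "bartlett_p": float(bartlett_p),
        "shapiro_p_workers": float(sw_w.pvalue),
        "shapiro_p_soldiers": float(sw_s.pvalue),
        "t_stat": float(t.statistic),
        "p_value": float(t.pvalue),
        "welch": welch,
    }


def fpkm(counts: pd.DataFrame, count_col: str = "counts",
         length_col: str = "length_bp",
         library_size: float | None = None) -> pd.Series:
    """Per-gene FPKM from raw counts and transcript lengths.

    ``FPKM_g = counts_g * 1e9 / (length_g * library_size)``; the library size
    defaults to the column sum of counts.  Zero library size is an error.
    """
    c = counts[count_col].astype(float)
    lengths = counts[length_col].astype(float)
    if (c < 0).any():
        raise ValueError("counts must be >= 0")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    if library_size is None:
        library_size = float(c.sum())
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    out = c * 1e9 / (lengths * library_size)
    out.name = "fpkm"
    return out
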