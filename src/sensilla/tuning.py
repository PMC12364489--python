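"""Odorant tuning metrics: response matrices, tuning curves, lifetime sparseness.

A receptor's breadth of tuning across an odorant panel is summarized by the
lifetime sparseness statistic

    S = (1 - (sum(r_i)/N)^2 / (sum(r_i^2)/N)) / (1 - 1/N)

with r_i the mean response to odorant i (negative responses clipped to zero by
default, since inhibitory responses would otherwise inflate the statistic).
S = 0 for a perfectly uniform response profile and S = 1 for a receptor that
responds to a single odorant only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "TuningSummary",
    "mean_responses",
    "tuning_curve",
    "lifetime_sparseness",
    "heatmap_table",
]


@dataclass
class ResponseMatrix:
    """Odorant x replicate table of delta spikes/s with a solvent reference.

    ``data`` is tidy: columns ``odorant``, ``replicate``,
    ``delta_spikes_per_s``.  ``solvent`` names the solvent row used for
    correction (it must be present until :meth:`solvent_corrected` drops it).
    ``dose_ng`` records the stimulus amount per filter paper; the default
    1000 ng corresponds to pipetting 10 ul of a 100 ng/ul dilution.
    """

    data: pd.DataFrame
    solvent: str = "hexane"
    dose_ng: float = 1000.0
    receptor: str | None = None

    REQUIRED = ("odorant", "replicate", "delta_spikes_per_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"response table missing columns: {missing}")
        if self.data.empty:
            raise ValueError("response table is empty")

    @property
    def odorants(self) -> list[str]:
        return sorted(self.data["odorant"].unique())

    def solvent_corrected(self) -> "ResponseMatrix":
        """Subtract the mean solvent response from every replicate.

        The solvent row itself is removed from the corrected table.
        """
        if self.solvent not in set(self.data["odorant"]):
            raise ValueError(f"solvent {self.solvent!r} not present in table")
        solvent_mean = self.data.loc[
            self.data["odorant"] == self.solvent, "delta_spikes_per_s"].mean()
        out = self.data[self.data["odorant"] != self.solvent].copy()
        out["delta_spikes_per_s"] = out["delta_spikes_per_s"] - solvent_mean
        return ResponseMatrix(out, solvent=self.solvent, dose_ng=self.dose_ng,
                              receptor=self.receptor)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, solvent: str = "hexane",
                 dose_ng: float = 1000.0,
                 receptor: str | None = None) -> "ResponseMatrix":
        return cls(pd.read_csv(path), solvent=solvent, dose_ng=dose_ng,
                   receptor=receptor)


@dataclass(frozen=True)
class TuningSummary:
    """Bell-ordered mean responses with the lifetime sparseness value."""

    ordered_responses: np.ndarray
    sparseness: float
    n_odorants: int


def mean_responses(matrix: ResponseMatrix,
                   odorants: list[str] | None = None) -> pd.DataFrame:
    """Per-odorant mean and SEM of delta spikes/s.

    Inputs are expected to be solvent-corrected already.  SEM is reported as
    NaN when an odorant has a single replicate.  If ``odorants`` is given,
    every listed odorant must be present; missing ones raise with their names.
    """
    if odorants is not None:
        missing = sorted(set(odorants) - set(matrix.data["odorant"]))
        if missing:
            raise ValueError(f"odorants missing from response table: {missing}")
    grouped = matrix.data.groupby("odorant")["delta_spikes_per_s"]
    out = grouped.agg(mean="mean", n="size",
                      sd=lambda x: x.std(ddof=1)).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["odorant", "mean", "sem", "n"]]


def tuning_curve(means: np.ndarray | pd.Series | dict) -> np.ndarray:
    """Bell ("tuning-curve") ordering of mean responses.

    The strongest response is placed at the center; the remaining responses
    are placed alternately to the right and to the left in descending order
    (right first), producing the symmetric bell shape conventional for
    receptor tuning curves.  Deterministic: ties keep their input order, and
    the stronger side of the bell is the right one.
    """
    if isinstance(means, dict):
        values = np.asarray(list(means.values()), dtype=float)
    else:
        values = np.asarray(means, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("need at least one response")
    desc = np.sort(values, kind="stable")[::-1]
    left: list[float] = []
    right: list[float] = []
    for i, v in enumerate(desc[1:]):
        (right if i % 2 == 0 else left).append(v)
    # left side ascends toward center, right side descends away from it
    return np.array(left[::-1] + [desc[0]] + right)


def lifetime_sparseness(means: np.ndarray | pd.Series | dict,
                        clip_negative: bool = True) -> float:
    """Lifetime sparseness S in [0, 1] of a mean-response profile.

    Negative (inhibitory) mean responses are clipped to 0 by default before
    evaluating the formula.  Raises if fewer than two odorants are given or
    if every response is zero after clipping (S undefined).
    """
    if isinstance(means, dict):
        r = np.asarray(list(means.values()), dtype=float)
    else:
        r = np.asarray(means, dtype=float).ravel()
    n = r.size
    if n < 2:
        raise ValueError("lifetime sparseness requires at least two odorants")
    if clip_negative:
        r = np.clip(r, 0.0, None)
    sum_sq = float(np.sum(r ** 2))
    if sum_sq == 0.0:
        raise ValueError("all responses are zero after clipping; "
                         "sparseness undefined")
    s = (1.0 - (np.sum(r) / n) ** 2 / (sum_sq / n)) / (1.0 - 1.0 / n)
    return float(s)


def tuning_summary(matrix: ResponseMatrix,
                   clip_negative: bool = True) -> TuningSummary:
    """Mean responses -> bell ordering + lifetime sparseness, in one call."""
    means = mean_responses(matrix)["mean"].to_numpy()
    return TuningSummary(ordered_responses=tuning_curve(means),
                         sparseness=lifetime_sparseness(means, clip_negative),
                         n_odorants=len(means))


def heatmap_table(matrices: dict[str, ResponseMatrix],
                  wide: bool = True) -> pd.DataFrame:
    """Combine per-receptor response matrices into a receptor x odorant table.

    All receptors must share the same odorant set; otherwise the error lists
    the set difference.  Returns a wide table (receptors as rows, odorants as
    columns, mean delta spikes/s as values) or the tidy long format.
    """
    if not matrices:
        raise ValueError("no response matrices given")
    odorant_sets = {name: set(m.data["odorant"]) for name, m in matrices.items()}
    reference = next(iter(odorant_sets.values()))
    for name, odors in odorant_sets.items():
        if odors != reference:
            raise ValueError(
                f"odorant panels differ for {name!r}: "
                f"missing {sorted(reference - odors)}, "
                f"extra {sorted(odors - reference)}")
    rows = []
    for name, matrix in sorted(matrices.items()):
        means = mean_responses(matrix)
        for _, rec in means.iterrows():
            rows.append((name, rec["odorant"], rec["mean"]))
    long = pd.DataFrame(rows, columns=["receptor", "odorant", "mean"])
    if not wide:
        return long
    return long.pivot(index="receptor", columns="odorant",
                      values="mean").sort_index()
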