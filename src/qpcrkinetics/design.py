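"""Experimental design description for a chondrogenesis qPCR time course.

A dataset is organized as cell types x time points x biological replicates,
optionally with an extra pre-pellet monolayer condition.  Time points are kept
as canonical string labels throughout the package (``"0"``, ``"1.5"``, ...,
``"336"`` and the literal ``"monolayer"``) so that CSV round trips are exact;
:func:`time_to_hours` converts back to numeric hours when ordering matters.
"""

from __future__ import annotations

from dataclasses import dataclass
#: Categorical label for the pre-pellet monolayer condition (not a numeric time).
MONOLAYER = "monolayer"

#: Default post-thaw pellet collection grid in hours (0 h is the baseline).
DEFAULT_TIME_POINTS_H: tuple[float, ...] = (0, 1.5, 3, 6, 12, 24, 48, 96, 168, 336)

#: Default cell-type labels: interzone, anlagen, dermal fibroblast.
DEFAULT_CELL_TYPES: tuple[str, ...] = ("IZ", "ANL", "FB")


def format_time(hours: float) -> str:
    """Canonical string label for a numeric time point (``6`` not ``6.0``)."""
    h = float(hours)
    return str(int(h)) if h == int(h) else repr(h)


def time_to_hours(label: str) -> float:
    """Numeric hours for a time label; raises ValueError for ``monolayer``."""
    if label == MONOLAYER:
        raise ValueError("monolayer is a categorical condition, not a numeric time")
    return float(label)


def time_sort_key(label: str) -> tuple[int, float]:
    """Sort key placing monolayer first, then numeric times ascending."""
    if label == MONOLAYER:
        return (0, 0.0)
    return (1, float(label))


@dataclass(frozen=True)
class SamplingDesign:
    """Cell types x time points x replicates layout of one experiment.

    Parameters
    ----------
    cell_types
        Ordered cell-type labels.
    time_points_h
        Strictly increasing non-negative hours; must contain 0 (the baseline
        against which all time contrasts are formed).
    monolayer_included
        Whether a pre-pellet monolayer condition was also sampled.
    n_replicates
        Biological replicates per (cell type, condition); at least 2 so that
        within-group variance is estimable.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS_H
    monolayer_included: bool = True
    n_replicates: int = 7

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "time_points_h", tuple(float(t) for t in self.time_points_h))
        if not self.cell_types:
            raise ValueError("at least one cell type is required")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell types must be unique")
        tp = self.time_points_h
        if any(t < 0 for t in tp):
            raise ValueError("time points must be non-negative hours")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        if 0.0 not in tp:
            raise ValueError("the 0 h baseline must be among the time points")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for variance estimation")

    @property
    def time_labels(self) -> tuple[str, ...]:
        """All condition labels in analysis order (monolayer first if present)."""
        labels = tuple(format_time(t) for t in self.time_points_h)
        return ((MONOLAYER,) if self.monolayer_included else ()) + labels

    @property
    def post_baseline_labels(self) -> tuple[str, ...]:
        """Pellet time points after 0 h — the grid on which onsets can occur."""
        return tuple(format_time(t) for t in self.time_points_h if t > 0)

    @property
    def n_conditions(self) -> int:
        return len(self.time_labels)

    @property
    def n_samples(self) -> int:
        """Total experimental samples (excludes calibrator and dilutions)."""
        return len(self.cell_types) * self.n_conditions * self.n_replicates

    def expected_cells(self) -> list[tuple[str, str, int]]:
        """Every (cell_type, time_label, replicate) cell the design implies."""
        return [
            (ct, t, r)
            for ct in self.cell_types
            for t in self.time_labels
            for r in range(1, self.n_replicates + 1)
        ]
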