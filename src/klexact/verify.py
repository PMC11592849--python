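"""Verification harness: closed form vs. quadrature oracle on parameter grids.

``run_paper_grids`` reproduces the published correctness check: for the
chi, exponential, generalized logistic (type I) and power function (type I)
families, one parameter is held at 1 while the other sweeps 1..100, in both
orientations, and the closed form is compared with the oracle at every grid
point.  ``run_sweep`` generalizes the same protocol to any family.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .closed_form import kld
from .oracle import QuadratureSettings, kld_numeric
from .registry import get_family

__all__ = ["GridRow", "GridReport", "run_sweep", "run_paper_grids"]


@dataclass(frozen=True)
class GridRow:
    p1: dict[str, float]
    p2: dict[str, float]
    closed_value: float | None
    oracle_value: float | None
    abs_diff: float | None
    method: str
    skipped_reason: str | None = None


@dataclass
class GridReport:
    family: str
    sweep: str
    rows: list[GridRow] = field(default_factory=list)

    @property
    def max_abs_diff(self) -> float:
        diffs = [r.abs_diff for r in self.rows if r.abs_diff is not None]
        return max(diffs) if diffs else math.nan

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("family,sweep,param_point,closed,oracle,abs_diff,method\n")
        for r in self.rows:
            if r.skipped_reason is not None:
                buf.write(
                    f"{self.family},{self.sweep},\"{_pt(r.p1, r.p2)}\","
                    f"skipped,skipped,skipped,{r.skipped_reason}\n"
                )
                continue
            buf.write(
                f"{self.family},{self.sweep},\"{_pt(r.p1, r.p2)}\","
                f"{r.closed_value:.17g},{r.oracle_value:.17g},"
                f"{r.abs_diff:.17g},{r.method}\n"
            )
        return buf.getvalue()


def _pt(p1: Mapping[str, float], p2: Mapping[str, float]) -> str:
    s1 = " ".join(f"{k}={v:g}" for k, v in p1.items())
    s2 = " ".join(f"{k}={v:g}" for k, v in p2.items())
    return f"f1({s1}) f2({s2})"


def _split_fixed(family: str, fixed: Mapping[str, float]):
    fam = get_family(family)
    p1: dict[str, float] = {}
    p2: dict[str, float] = {}
    for key, val in fixed.items():
        name = key
        side2 = False
        if key.startswith("f2_"):
            name, side2 = key[3:], True
        in1 = name in fam.param_names
        in2 = name in fam.alias_names
        shared = name in fam.shared_names
        if shared:
            p1[name] = val
            p2[name] = val
        elif side2 or (in2 and not in1):
            p2[name] = val
        elif in1:
            p1[name] = val
        else:
            raise ValueError(f"{family}: unknown parameter {key!r}")
    return fam, p1, p2


def run_sweep(
    family: str,
    fixed: Mapping[str, float],
    swept: str,
    values: Iterable[float],
    settings: QuadratureSettings | None = None,
) -> GridReport:
    """Sweep one parameter, compare closed form and oracle at each point.

    ``fixed`` holds every other parameter: f1-column symbols set the first
    density, f2-column symbols the second (prefix ``f2_`` disambiguates
    families whose two densities use the same symbols).  Inadmissible grid
    points are recorded as skipped rows, not raised.
    """
    fam, p1_fixed, p2_fixed = _split_fixed(family, fixed)
    name = swept[3:] if swept.startswith("f2_") else swept
    to_f2 = (
        swept.startswith("f2_")
        or (name in fam.alias_names and name not in fam.param_names)
    )
    settings = settings or QuadratureSettings()
    report = GridReport(family=family, sweep=f"{swept} over given values")
    for v in values:
        p1 = dict(p1_fixed)
        p2 = dict(p2_fixed)
        (p2 if to_f2 else p1)[name] = float(v)
        if name in fam.shared_names:
            p1[name] = float(v)
            p2[name] = float(v)
        try:
            res = kld(family, p1, p2)
            ora, _ = kld_numeric(family, p1, family, p2, settings=settings)
        except ValueError as exc:
            report.rows.append(
                GridRow(p1, p2, None, None, None, "invalid", str(exc))
            )
            continue
        diff = abs(res.value - ora) if math.isfinite(res.value) else math.inf
        report.rows.append(
            GridRow(p1, p2, res.value, ora, diff, res.method)
        )
    return report


_PAPER_GRIDS = (
    ("chi", {"m": 1.0}, "n"),
    ("chi", {"n": 1.0}, "m"),
    ("exponential", {"a": 1.0}, "b"),
    ("exponential", {"b": 1.0}, "a"),
    ("generalized_logistic_1", {"a": 1.0}, "b"),
    ("generalized_logistic_1", {"b": 1.0}, "a"),
    ("power_function_1", {"a": 1.0}, "b"),
    ("power_function_1", {"b": 1.0}, "a"),
)


def plot_report(report: GridReport, path: str) -> None:
    """Optional: swept value vs. |closed - oracle|, one panel per report.

    Requires matplotlib (an optional dependency); mirrors the published
    difference figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [i + 1 for i, r in enumerate(report.rows) if r.abs_diff is not None]
    ys = [r.abs_diff for r in report.rows if r.abs_diff is not None]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(xs, ys, ".", ms=4)
    ax.set_yscale("log")
    ax.set_xlabel("grid point")
    ax.set_ylabel("|closed - oracle|")
    ax.set_title(f"{report.family}: {report.sweep}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_paper_grids() -> list[GridReport]:
    """The eight published verification sweeps (fixed = 1, other = 1..100)."""
    values = [float(k) for k in range(1, 101)]
    out = []
    for family, fixed, swept in _PAPER_GRIDS:
        rep = run_sweep(family, fixed, swept, values)
        rep.sweep = (
            f"{next(iter(fixed))}={next(iter(fixed.values())):g}, "
            f"{swept}=1..100"
        )
        out.append(rep)
    return out
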