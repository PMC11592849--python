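"""Plain key=value configuration for evaluation policies.

Recognized keys (all optional)::

    series.rel_tol            relative series truncation tolerance
    series.abs_tol            absolute series truncation tolerance
    series.max_terms          series term budget
    series.consecutive_small  stopping-rule run length
    deriv.step                finite-difference step (default: auto)
    deriv.richardson_levels   Richardson extrapolation levels
    quad.rel_tol              quadrature relative tolerance
    quad.abs_tol              quadrature absolute tolerance
    quad.max_subdivisions     quadrature subdivision budget

Lines starting with ``#`` and blank lines are ignored.
"""

from __future__ import annotations

from dataclasses import replace

from .oracle import QuadratureSettings
from .special import DerivPolicy, SeriesPolicy

__all__ = ["load_config"]


def load_config(path: str) -> tuple[SeriesPolicy, DerivPolicy, QuadratureSettings]:
    series = SeriesPolicy()
    deriv = DerivPolicy()
    quad = QuadratureSettings()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            try:
                if key == "series.rel_tol":
                    series = replace(series, rel_tol=float(raw))
                elif key == "series.abs_tol":
                    series = replace(series, abs_tol=float(raw))
                elif key == "series.max_terms":
                    series = replace(series, max_terms=int(raw))
                elif key == "series.consecutive_small":
                    series = replace(series, consecutive_small=int(raw))
                elif key == "deriv.step":
                    deriv = replace(deriv, step=float(raw))
                elif key == "deriv.richardson_levels":
                    deriv = replace(deriv, richardson_levels=int(raw))
                elif key == "quad.rel_tol":
                    quad = replace(quad, rel_tol=float(raw))
                elif key == "quad.abs_tol":
                    quad = replace(quad, abs_tol=float(raw))
                elif key == "quad.max_subdivisions":
                    quad = replace(quad, max_subdivisions=int(raw))
                else:
                    raise ValueError(f"unknown key {key!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return series, deriv, quad
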