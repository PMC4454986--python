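"""Summaries of Monte-Carlo output: modal value, 95% interval, 2-sf rounding.

Simulated flow and concentration distributions are heavy right-tailed and
often contain a point mass at exactly zero (pathways cut off by
transformation).  The headline statistics reported per quantity are the
*modal value* — the most probable outcome — and the empirical 2.5%/97.5%
quantiles framing the 95% range.

Mode estimation: if more than half the samples are exactly zero the mode
is 0; otherwise the strictly positive samples are histogrammed with bins
equal-width in log10 (Freedman–Diaconis width); the per-bin density *in
linear units* (count ÷ linear bin width) is computed, and the estimate is
the density-weighted geometric center of the bins within 90% of the peak
density.  Two details matter: the linear-density correction (the
count-densest log bin estimates the mode of log X, i.e. the median of X,
not the mode of X) and the near-maximal-region averaging (FD bins are
narrow enough that the single densest bin wanders noticeably under
multinomial noise on the flat top of heavy-tailed densities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concentrations import concentration_samples
from .flow_system import ENV_MEDIA
from .monte_carlo import MCResult


def interval_95(samples) -> tuple[float, float]:
    """Empirical (2.5%, 97.5%) quantiles, linear interpolation between
    order statistics."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("interval_95 needs at least 2 samples")
    lo, hi = np.quantile(x, [0.025, 0.975])
    return float(lo), float(hi)


def zero_fraction(samples) -> float:
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample vector")
    return float(np.mean(x == 0.0))


def mode_estimate(samples) -> float:
    """Modal value of a nonnegative Monte-Carlo sample vector.

    Zero-majority samples report a mode of exactly 0 (the most frequent
    outcome when e.g. transformation eliminates a pathway in most
    realizations); otherwise see the module docstring for the log-scale
    histogram rule.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("mode_estimate needs at least 10 samples")
    if np.any(x < 0):
        raise ValueError("samples must be nonnegative")
    if zero_fraction(x) > 0.5:
        return 0.0
    pos = x[x > 0]
    y = np.log10(pos)
    q75, q25 = np.percentile(y, [75, 25])
    h = 2.0 * (q75 - q25) / pos.size ** (1.0 / 3.0)  # Freedman–Diaconis
    ymin, ymax = y.min(), y.max()
    if h <= 0 or ymax == ymin:
        # (near-)degenerate positives: most common value
        vals, counts = np.unique(pos, return_counts=True)
        return float(vals[np.argmax(counts)])
    nbins = max(1, int(np.ceil((ymax - ymin) / h)))
    counts, bin_edges = np.histogram(y, bins=nbins, range=(ymin, ymax))
    widths_linear = np.diff(10.0 ** bin_edges)
    dens = counts / widths_linear
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    # single-bin argmax is noisy on the flat top of heavy-tailed densities;
    # the density-weighted center of the near-maximal region is stable
    sel = dens >= 0.9 * dens.max()
    return float(10.0 ** np.average(mids[sel], weights=dens[sel]))


def round_2sf(value: float) -> float:
    """Round to two significant digits (round-half-even); 0 stays 0."""
    if value < 0:
        raise ValueError("round_2sf expects nonnegative values")
    if value == 0 or not np.isfinite(value):
        return float(value)
    exp = int(np.floor(np.log10(value)))
    # guard against log10 round-off at exact powers of ten
    if value / 10.0 ** exp >= 10.0:
        exp += 1
    elif value / 10.0 ** exp < 1.0:
        exp -= 1
    # Python's round() is correctly rounded in decimal, half-to-even
    return float(round(value, 1 - exp))


@dataclass(frozen=True)
class ConcentrationSummary:
    compartment_id: str
    unit: str
    basis: str
    mode: float
    q025: float
    q975: float
    n_iter: int
    zero_fraction: float


def summarize_samples(cid: str, unit: str, basis: str, values: np.ndarray) -> ConcentrationSummary:
    lo, hi = interval_95(values)
    return ConcentrationSummary(
        compartment_id=cid,
        unit=unit,
        basis=basis,
        mode=mode_estimate(values),
        q025=lo,
        q975=hi,
        n_iter=int(np.size(values)),
        zero_fraction=zero_fraction(values),
    )


def concentration_table(mc: MCResult, ramp: str = "linear_from_2000", rounded: bool = True) -> pd.DataFrame:
    """Concentration summary table (mode / 95% range per compartment & basis)."""
    rows = []
    for cs in concentration_samples(mc, ramp=ramp):
        s = summarize_samples(cs.compartment_id, cs.unit, cs.basis, cs.values)
        rows.append(
            {
                "compartment": s.compartment_id,
                "basis": s.basis,
                "unit": s.unit,
                "mode": round_2sf(s.mode) if rounded else s.mode,
                "q025": round_2sf(s.q025) if rounded else s.q025,
                "q975": round_2sf(s.q975) if rounded else s.q975,
                "zero_fraction": s.zero_fraction,
                "n_iter": s.n_iter,
            }
        )
    return pd.DataFrame(rows)


def flow_table(mc: MCResult) -> pd.DataFrame:
    """Per-edge modal flow and 95% interval (t/y).

    Modal values are per-edge statistics of the joint simulation; they show
    the most likely flow at each edge individually and need not close an
    exact mass balance jointly.
    """
    if mc.n_iter < 1 or not mc.edges:
        raise ValueError("empty Monte-Carlo result")
    rows = []
    for i, (o, d) in enumerate(mc.edges):
        f = mc.edge_flows[:, i]
        lo, hi = interval_95(f) if mc.n_iter >= 2 else (float(f[0]), float(f[0]))
        rows.append(
            {
                "origin": o,
                "destination": d,
                "mode_t_per_y": mode_estimate(f) if mc.n_iter >= 10 else float(np.median(f)),
                "q025_t_per_y": lo,
                "q975_t_per_y": hi,
                "mean_t_per_y": float(f.mean()),
            }
        )
    return pd.DataFrame(rows)


def _env_edge_indices(mc: MCResult) -> list[int]:
    """Edges carrying *primary* release: technical origin → environmental
    destination."""
    byid = mc.scenario.by_id()
    out = []
    for i, (o, d) in enumerate(mc.edges):
        if byid[o].medium not in ENV_MEDIA and byid[d].medium in ENV_MEDIA:
            out.append(i)
    return out


def source_receiver_table(mc: MCResult) -> pd.DataFrame:
    """Per receiving environmental compartment, the percentage contributed
    by each technical source pathway (shares of modal flows; they sum to
    100% per receiver before rounding)."""
    idxs = _env_edge_indices(mc)
    rows = []
    by_dest: dict[str, list[int]] = {}
    for i in idxs:
        by_dest.setdefault(mc.edges[i][1], []).append(i)
    for dest, eis in by_dest.items():
        modes = np.array(
            [mode_estimate(mc.edge_flows[:, i]) for i in eis]
        )
        total = modes.sum()
        for i, m in zip(eis, modes):
            rows.append(
                {
                    "receiver": dest,
                    "source": mc.edges[i][0],
                    "share_pct": 100.0 * m / total if total > 0 else 0.0,
                    "modal_flow_t_per_y": float(m),
                }
            )
    return pd.DataFrame(rows)


def release_share_samples(mc: MCResult, media: tuple[str, ...]) -> np.ndarray:
    """Per-iteration share of total primary environmental release received
    by compartments of the given media (e.g. ``("soil",)``)."""
    byid = mc.scenario.by_id()
    idxs = _env_edge_indices(mc)
    if not idxs:
        raise ValueError("scenario has no technical→environmental edges")
    sel = [i for i in idxs if byid[mc.edges[i][1]].medium in media]
    total = mc.edge_flows[:, idxs].sum(axis=1)
    part = mc.edge_flows[:, sel].sum(axis=1) if sel else np.zeros(mc.n_iter)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, part / np.where(total > 0, total, 1.0), 0.0)
    return share


def destination_share_samples(mc: MCResult, origin: str, destinations: tuple[str, ...]) -> np.ndarray:
    """Per-iteration share of ``origin``'s outflow routed directly to the
    given destinations (e.g. the waste pathways of the use phase)."""
    idxs = [i for i, (o, _) in enumerate(mc.edges) if o == origin]
    if not idxs:
        raise ValueError(f"no outgoing edges from {origin!r}")
    sel = [i for i in idxs if mc.edges[i][1] in destinations]
    total = mc.edge_flows[:, idxs].sum(axis=1)
    part = mc.edge_flows[:, sel].sum(axis=1) if sel else np.zeros(mc.n_iter)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, part / np.where(total > 0, total, 1.0), 0.0)
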