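"""Model / Results interface for the remnant-network analysis.

:class:`RemnantNetworkModel` is built from a functional connectivity
network and a set of biophysical reference networks; :meth:`fit` removes
each reference network's strongest edges at matched density, measures the
percent shift of the requested graph features, benchmarks every shift
against a null model, and returns an :class:`RFNResults` object carrying
the estimates, their empirical p-values and a ``summary()`` table.
Gradient shifts and search-information FC prediction hang off the same
pair of objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import metrics as gm
from .gradients import affinity, diffusion_map, gradient_shift, procrustes_align
from .network import (
    RemnantNetwork,
    WeightedNetwork,
    clip_negative,
    density,
    to_magnitude,
)
from .nulls import NullDistribution, empirical_p, random_removal_null
from .nulls import hemisphere_matched_null, rewire_preserving_degree
from .parcellation import Parcellation
from .remnant import build_rfn, shift_ratio, strongest_edge_benchmark
from .search_info import nodewise_r2, reverse_si, search_info_matrix

__all__ = ["RemnantNetworkModel", "RFNResults", "DEFAULT_DENSITY"]

# average structural-connectome density reported for the source cohort
DEFAULT_DENSITY = 0.1607


class RemnantNetworkModel:
    """Quantifies how biophysical networks shape a functional connectome.

    Parameters
    ----------
    fc
        The functional connectivity network (signed or unsigned).
    biophysical
        Mapping of tag -> reference network (e.g. SC, DC, GC, RC and the
        distance-corrected GCd / RCd).
    parcellation
        Optional region metadata; required for the hemisphere-matched null.
    density
        Matched removal density. Defaults to the measured density of the
        supplied SC network if it is sparse, else 0.1607.
    convention
        FC sign handling: "magnitude" (|r|, the main convention) or
        "clip_negative" (zero-thresholded).
    """

    def __init__(
        self,
        fc: WeightedNetwork,
        biophysical: Mapping[str, WeightedNetwork],
        parcellation: Parcellation | None = None,
        density_matched: float | None = None,
        convention: str = "magnitude",
    ):
        if convention not in {"magnitude", "clip_negative"}:
            raise ValueError("convention must be 'magnitude' or 'clip_negative'")
        self.convention = convention
        self.fc = to_magnitude(fc) if convention == "magnitude" else clip_negative(fc)
        self.biophysical = dict(biophysical)
        if not self.biophysical:
            raise ValueError("need at least one biophysical network")
        for tag, net in self.biophysical.items():
            if net.n != self.fc.n:
                raise ValueError(f"network {tag!r} does not match FC dimensions")
        self.parcellation = parcellation
        if density_matched is None:
            sc = self.biophysical.get("SC")
            if sc is not None and density(sc) < 0.999:
                density_matched = density(sc)
            else:
                density_matched = DEFAULT_DENSITY
        if not (0 < density_matched < 1):
            raise ValueError("matched density must lie in (0, 1)")
        self.density_matched = float(density_matched)

    # -- construction -----------------------------------------------------
    def remnants(self) -> dict[str, RemnantNetwork]:
        """One RFN per biophysical source at the matched density."""
        return {
            tag: build_rfn(self.fc, net, self.density_matched)
            for tag, net in self.biophysical.items()
        }

    # -- estimation --------------------------------------------------------
    def fit(
        self,
        metrics: tuple[str, ...] | None = None,
        null: str = "random",
        n_null: int = 1000,
        seed: int = 0,
        n_restarts: int = 20,
        null_restarts: int = 3,
        benchmark: bool = True,
    ) -> "RFNResults":
        """Estimate percent shifts with null-model significance.

        ``null`` is one of "random", "rewired", "hemisphere" or "none".
        Modularity uses seeded Louvain with ``n_restarts`` restarts for the
        observed values; null-distribution evaluations use the cheaper
        ``null_restarts`` since each of the (typically 1000) iterations
        re-optimizes the partition.  ``benchmark`` additionally evaluates
        the strongest-edge removal (the top-density FC edges) and the
        shift ratios against it.
        """
        metrics = tuple(metrics) if metrics is not None else gm.METRICS
        unknown = set(metrics) - set(gm.METRICS)
        if unknown:
            raise KeyError(f"unknown metrics: {sorted(unknown)}")
        if null not in {"random", "rewired", "hemisphere", "none"}:
            raise ValueError(f"unknown null model {null!r}")
        rng = np.random.default_rng(seed)
        mkw = {"n_restarts": n_restarts, "seed": int(rng.integers(2**31 - 1))}
        nkw = {"n_restarts": null_restarts, "seed": mkw["seed"]}

        def value(net, name):
            return gm.evaluate_metric(net, name, **(mkw if name == "modularity" else {}))

        full_values = {name: value(self.fc, name) for name in metrics}
        remnants = self.remnants()
        if benchmark:
            remnants = dict(remnants)
            remnants["TOP_FC"] = strongest_edge_benchmark(
                self.fc, self.density_matched
            )

        rows = []
        nulls: dict[tuple, NullDistribution] = {}
        regional: dict[tuple, np.ndarray] = {}
        for tag, rfn in remnants.items():
            null_masked = self._null_values(
                rfn, metrics, null, n_null, rng, nkw
            ) if null != "none" and tag != "TOP_FC" else {}
            for name in metrics:
                v_full = full_values[name]
                v_rfn = value(rfn.result, name)
                delta = gm.metric_shift(v_full, v_rfn)
                p = np.nan
                if name in null_masked:
                    nd = null_masked[name]
                    nulls[(name, tag)] = nd
                    p = empirical_p(delta, nd)
                rows.append(
                    {
                        "metric": name,
                        "source": tag,
                        "value_full": v_full,
                        "value_rfn": v_rfn,
                        "delta_pct": delta,
                        "p": p,
                    }
                )
                if name in gm.REGIONAL_METRICS:
                    regional[(name, tag)] = gm.regional_shift(
                        gm.REGIONAL_METRICS[name](self.fc),
                        gm.REGIONAL_METRICS[name](rfn.result),
                    )
        table = pd.DataFrame(rows)
        return RFNResults(
            model=self,
            table=table,
            nulls=nulls,
            regional_shifts=regional,
            remnants=remnants,
            null_model=null,
            n_null=n_null if null != "none" else 0,
            seed=seed,
        )

    def _null_values(self, rfn, metrics, null, n_null, rng, mkw):
        """Per-metric null shift distributions for one RFN's removal."""
        out = {}
        mask = rfn.mask
        if null == "rewired":
            # rewire once per iteration; evaluate all metrics on each draw
            base = {m: gm.evaluate_metric(self.fc, m, **(mkw if m == "modularity" else {})) for m in metrics}
            draws = {m: np.empty(n_null) for m in metrics}
            for it in range(n_null):
                rw = rewire_preserving_degree(
                    mask, seed=int(rng.integers(2**31 - 1))
                )
                from .network import apply_mask

                net = apply_mask(self.fc, rw)
                for m in metrics:
                    v = gm.evaluate_metric(net, m, **(mkw if m == "modularity" else {}))
                    draws[m][it] = 100.0 * (v - base[m]) / base[m]
            for m in metrics:
                out[m] = NullDistribution(
                    model="rewired",
                    metric=m,
                    values=draws[m],
                    iterations=n_null,
                    seed=-1,
                )
            return out
        for m in metrics:
            fn = lambda net, _m=m: gm.evaluate_metric(
                net, _m, **(mkw if _m == "modularity" else {})
            )
            s = int(rng.integers(2**31 - 1))
            if null == "random":
                out[m] = random_removal_null(
                    self.fc, rfn.n_removed, fn, iters=n_null, seed=s, metric=m
                )
            else:  # hemisphere
                if self.parcellation is None:
                    raise ValueError("hemisphere null requires a parcellation")
                out[m] = hemisphere_matched_null(
                    self.fc, mask, self.parcellation, fn,
                    iters=n_null, seed=s, metric=m,
                )
        return out

    # -- companion analyses -------------------------------------------------
    def gradient_analysis(self, k: int = 2, row_sparsity: float = 0.9) -> pd.DataFrame:
        """Gradient shifts delta = 1 - |R| per source and component."""
        g_full = diffusion_map(affinity(self.fc, row_sparsity), k=k)
        rows = []
        for tag, rfn in self.remnants().items():
            g = diffusion_map(affinity(rfn.result, row_sparsity), k=k)
            g = procrustes_align(g, g_full)
            for c in range(k):
                rows.append(
                    {
                        "source": tag,
                        "gradient": c + 1,
                        "delta": gradient_shift(g_full, g, component=c),
                        "variance_fraction_full": g_full.variance_fraction[c],
                        "variance_fraction_rfn": g.variance_fraction[c],
                    }
                )
        return pd.DataFrame(rows)

    def search_information_analysis(self) -> pd.DataFrame:
        """Nodewise R^2 of FC profiles predicted from each source's SI."""
        rows = []
        for tag, net in self.biophysical.items():
            si = search_info_matrix(net)
            res = nodewise_r2(reverse_si(si), self.fc)
            rows.append(
                {
                    "source": tag,
                    "mean_r2": res["mean"],
                    "sd_r2": res["sd"],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RFNResults:
    """Fitted removal shifts, null distributions and diagnostics."""

    model: RemnantNetworkModel
    table: pd.DataFrame
    nulls: dict
    regional_shifts: dict
    remnants: dict
    null_model: str
    n_null: int
    seed: int

    def deltas(self) -> pd.DataFrame:
        """Percent shifts, metrics x sources."""
        return self.table.pivot(index="metric", columns="source", values="delta_pct")

    def pvalues(self) -> pd.DataFrame:
        return self.table.pivot(index="metric", columns="source", values="p")

    def shift_ratios(self) -> pd.DataFrame:
        """Each source's shift relative to the strongest-edge benchmark."""
        if "TOP_FC" not in set(self.table["source"]):
            raise ValueError("fit without benchmark; ratios unavailable")
        d = self.deltas()
        top = d["TOP_FC"]
        others = d.drop(columns="TOP_FC")
        return others.apply(lambda col: col.combine(top, shift_ratio))

    def mean_abs_shift(self, by: str = "source") -> pd.Series:
        """Mean |Delta| marginal over metrics (by='source') or sources."""
        sub = self.table[self.table["source"] != "TOP_FC"]
        axis = "source" if by == "source" else "metric"
        return sub.groupby(axis)["delta_pct"].apply(lambda s: s.abs().mean())

    def summary(self) -> str:
        lines = [
            "Remnant Functional Network analysis",
            "=" * 64,
            f"regions: {self.model.fc.n}   FC convention: {self.model.convention}",
            f"matched removal density: {self.model.density_matched:.4f} "
            f"(RFN density {density(next(iter(self.remnants.values())).result):.4f})",
            f"null model: {self.null_model} ({self.n_null} iterations, seed {self.seed})",
            "",
            "Percent shift (delta) by metric and removed source:",
            self.deltas().round(3).to_string(),
        ]
        p = self.pvalues()
        if p.notna().to_numpy().any():
            lines += ["", "Empirical p (add-one, one-sided on |delta|):",
                      p.round(4).to_string()]
        lines += ["", "Mean |delta| per source (%):",
                  self.mean_abs_shift().round(3).to_string()]
        return "\n".join(lines)
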