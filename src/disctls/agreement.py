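"""Method-agreement statistics for paired volume measurements.

Implements the full validation suite for comparing TLS-estimated disc
volumes (y) against water-displacement reference volumes (x): regression
metrics (R², RMSE, RE, Bias, rRMSE), Bland–Altman limits of agreement,
Lin's concordance correlation coefficient, a gauge-repeatability (GRR)
variance decomposition of the replicate reference measurements, and
non-parametric group comparisons (Kruskal–Wallis across species,
pairwise Mann–Whitney U).

The module follows the statsmodels idiom: build a :class:`VolumeAgreement`
model from a sample table, call :meth:`~VolumeAgreement.fit`, and read the
estimates off the returned :class:`AgreementResults` (or print
``results.summary()``).  The elementary statistics are also exposed as plain
functions.

Conventions the literature leaves open are explicit and echoed in every
report: the difference direction for Bland–Altman (default estimated −
observed), the variance denominator for the CCC (default population, the
convention under which the concordance estimator is defined), and tie
correction for the rank tests (default on).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DiscSample

__all__ = [
    "Conventions",
    "DegenerateDataError",
    "regression_metrics",
    "bland_altman",
    "ccc",
    "grr",
    "kruskal_wallis",
    "mann_whitney_u",
    "holm_adjust",
    "VolumeAgreement",
    "AgreementResults",
    "build_report",
]


class DegenerateDataError(ValueError):
    """Statistic undefined on this input (zero variance, all-tied ranks, …)."""


@dataclass
class Conventions:
    diff_direction: str = "est_minus_obs"   # or "obs_minus_est"
    variance_mode: str = "population"       # CCC denominators: "population" (n) or "sample" (n-1)
    tie_correction: bool = True             # rank tests

    def __post_init__(self) -> None:
        if self.diff_direction not in ("est_minus_obs", "obs_minus_est"):
            raise ValueError(f"unknown diff_direction {self.diff_direction!r}")
        if self.variance_mode not in ("population", "sample"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")


def _pair(observed, estimated):
    x = np.asarray(observed, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observed and estimated must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 paired samples")
    return x, y


def regression_metrics(observed: Sequence[float], estimated: Sequence[float]) -> Dict[str, float]:
    """R², RMSE, RE, Bias and rRMSE for estimated (y) against observed (x).

    R² uses the residual-vs-total decomposition 1 − Σ(y−x)²/Σ(y−ȳ)²;
    RE averages the relative differences (x−y)/y; Bias is the mean of y−x;
    rRMSE normalises RMSE by the mean *observed* volume, in percent.
    """
    x, y = _pair(observed, estimated)
    n = x.size
    sse = float(np.sum((y - x) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        if sse == 0:
            r2 = 1.0   # estimated == observed == constant: perfect agreement
        else:
            raise DegenerateDataError("R² undefined: zero variance in estimated values")
    else:
        r2 = 1.0 - sse / sst
    if np.any(y == 0) or np.any(x == 0):
        raise DegenerateDataError("RE undefined with zero volumes")
    rmse = float(np.sqrt(sse / n))
    xbar = float(x.mean())
    if xbar == 0:
        raise DegenerateDataError("rRMSE undefined: zero mean observed volume")
    return {
        "n": n,
        "r_squared": r2,
        "rmse": rmse,
        "re": float(np.mean((x - y) / y)),
        "bias": float(np.mean(y - x)),
        "rrmse": rmse / xbar * 100.0,
    }


def bland_altman(observed: Sequence[float], estimated: Sequence[float],
                 conventions: Optional[Conventions] = None) -> Dict[str, object]:
    """Mean difference, SD of differences and 95 % limits of agreement d̄ ± 1.96 s.

    ``s`` uses the sample (n−1) denominator.  Also returns the per-pair
    (mean, difference) coordinates for the Bland–Altman plot.
    """
    conv = conventions or Conventions()
    x, y = _pair(observed, estimated)
    d = (y - x) if conv.diff_direction == "est_minus_obs" else (x - y)
    dbar = float(d.mean())
    s = float(d.std(ddof=1))
    return {
        "mean_diff": dbar,
        "sd_diff": s,
        "uloa": dbar + 1.96 * s,
        "lloa": dbar - 1.96 * s,
        "pair_means": (x + y) / 2.0,
        "pair_diffs": d,
        "diff_direction": conv.diff_direction,
    }


def ccc(observed: Sequence[float], estimated: Sequence[float],
        conventions: Optional[Conventions] = None) -> float:
    """Lin's concordance correlation coefficient ρc = 2ρσxσy / (σx²+σy²+(μx−μy)²)."""
    conv = conventions or Conventions()
    x, y = _pair(observed, estimated)
    ddof = 0 if conv.variance_mode == "population" else 1
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    if vx == 0 or vy == 0:
        if np.array_equal(x, y):
            return 1.0
        raise DegenerateDataError("CCC undefined: zero variance")
    denom = x.size if ddof == 0 else x.size - 1
    cov = float(np.sum((x - x.mean()) * (y - y.mean())) / denom)
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def grr(replicates: Sequence[Sequence[float]]) -> Dict[str, float]:
    """Gauge repeatability from a parts × repeats study (one-factor random effects).

    ``replicates[i]`` holds the repeated measurements of part i.  Variance
    components come from the ANOVA mean squares (unbalanced designs handled
    through the effective replicate count n₀); negative part-variance
    estimates are truncated at zero.  GRR% = σ²_repeatability / σ²_total × 100
    — with a single gauge and operator the measurement-system variance is the
    repeatability variance.
    """
    groups = [np.asarray(g, dtype=float) for g in replicates]
    p = len(groups)
    if p < 2:
        raise ValueError("GRR needs at least 2 parts")
    if any(g.size < 2 for g in groups):
        raise ValueError("GRR needs at least 2 repeats per part")
    ns = np.array([g.size for g in groups], dtype=float)
    N = ns.sum()
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_within = ss_within / (N - p)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ms_between = ss_between / (p - 1)
    n0 = (N - float(np.sum(ns**2)) / N) / (p - 1)
    var_repeat = ms_within
    var_parts = max((ms_between - ms_within) / n0, 0.0)
    total = var_repeat + var_parts
    if total == 0:
        raise DegenerateDataError("GRR undefined: no variation at all")
    return {
        "grr_percent": var_repeat / total * 100.0,
        "var_repeatability": var_repeat,
        "var_parts": var_parts,
        "var_total": total,
        "n_parts": p,
    }


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   conventions: Optional[Conventions] = None) -> Dict[str, float]:
    """Kruskal–Wallis H with mid-ranks, optional tie correction and χ² p-value."""
    conv = conventions or Conventions()
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in gs):
        raise ValueError("every group must be non-empty")
    k = len(gs)
    if k == 1:
        return {"H": 0.0, "p": 1.0}
    pooled = np.concatenate(gs)
    N = pooled.size
    if N < 3:
        raise ValueError("need N >= 3 pooled observations")
    ranks = sps.rankdata(pooled)
    H = 0.0
    start = 0
    for g in gs:
        r = ranks[start:start + g.size]
        H += r.sum() ** 2 / g.size
        start += g.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    if conv.tie_correction:
        corr = 1.0 - _tie_term(pooled) / (N**3 - N)
        if corr == 0:
            raise DegenerateDataError("all pooled values identical: H undefined")
        H /= corr
    return {"H": float(H), "p": float(sps.chi2.sf(H, k - 1))}


def _mwu_exact_p(u_obs: float, n1: int, n2: int) -> float:
    """Two-sided exact p by full enumeration of the C(n1+n2, n1) rank splits.

    Uses the symmetry of the null distribution of U around n1·n2/2:
    p = P(|U − n1n2/2| ≥ |u_obs − n1n2/2|).
    """
    N = n1 + n2
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid)
    hits = 0
    for subset in combinations(range(N), n1):
        r1 = sum(subset) + n1  # ranks are subset indices + 1
        u = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
        if abs(u - mid) >= dev - 1e-12:
            hits += 1
    return hits / comb(N, n1)


def mann_whitney_u(group1: Sequence[float], group2: Sequence[float],
                   conventions: Optional[Conventions] = None) -> Dict[str, float]:
    """Mann–Whitney U from rank sums: U = n₁n₂ + n₁(n₁+1)/2 − R₁.

    Reports the smaller of the two one-sided statistics as ``U`` alongside
    both one-sided values.  The two-sided p-value is exact (full enumeration)
    for n₁+n₂ ≤ 12 without ties, otherwise a normal approximation with
    tie-adjusted variance and continuity correction.
    """
    conv = conventions or Conventions()
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u_formula = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u_other = n1 * n2 - u_formula
    u_min = min(u_formula, u_other)
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= 12 and not has_ties:
        p = _mwu_exact_p(u_formula, n1, n2)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        tie = _tie_term(pooled) if conv.tie_correction else 0.0
        N = n1 + n2
        var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var == 0:
            return {"U": u_min, "U1": u_formula, "U2": u_other, "p": 1.0,
                    "method": "degenerate"}
        z = (abs(u_formula - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        method = "normal_tie_corrected"
    return {"U": float(u_min), "U1": float(u_formula), "U2": float(u_other),
            "p": float(p), "method": method}


def holm_adjust(pvalues: Sequence[float]) -> List[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class VolumeAgreement:
    """Agreement model between TLS volume estimates and reference volumes.

    Parameters
    ----------
    data : DataFrame with columns ``id, species, estimated_volume,
        reference_volume`` and optionally ``rep1..rep3``, or a sequence of
        :class:`~disctls.io.DiscSample`.
    conventions : open-choice conventions; defaults documented on
        :class:`Conventions`.
    """

    def __init__(self, data: Union[pd.DataFrame, Sequence[DiscSample]],
                 conventions: Optional[Conventions] = None):
        if isinstance(data, pd.DataFrame):
            df = data.copy()
            if "reference_volume" not in df.columns:
                reps = [c for c in ("rep1", "rep2", "rep3") if c in df.columns]
                if not reps:
                    raise ValueError("need reference_volume or rep1..rep3 columns")
                df["reference_volume"] = df[reps].mean(axis=1)
        else:
            rows = []
            for s in data:
                reps = list(s.reference_replicates) + [np.nan] * (3 - len(s.reference_replicates))
                rows.append({"id": s.id, "species": s.species,
                             "estimated_volume": s.estimated_volume,
                             "reference_volume": s.reference_volume,
                             "rep1": reps[0], "rep2": reps[1], "rep3": reps[2]})
            df = pd.DataFrame(rows)
        if len(df) < 2:
            raise ValueError("need at least 2 samples")
        self.data = df
        self.conventions = conventions or Conventions()

    @classmethod
    def from_samples(cls, samples: Sequence[DiscSample],
                     conventions: Optional[Conventions] = None) -> "VolumeAgreement":
        return cls(samples, conventions)

    @classmethod
    def from_csv(cls, path, conventions: Optional[Conventions] = None) -> "VolumeAgreement":
        from .io import read_samples_table
        return cls(read_samples_table(path), conventions)

    def fit(self) -> "AgreementResults":
        df = self.data
        conv = self.conventions
        notes: List[str] = []
        x = df["reference_volume"].to_numpy(float)
        y = df["estimated_volume"].to_numpy(float)

        overall = regression_metrics(x, y)
        ba = bland_altman(x, y, conv)
        try:
            rho_c = ccc(x, y, conv)
        except DegenerateDataError as exc:
            rho_c = None
            notes.append(f"CCC not applicable: {exc}")

        rep_cols = [c for c in ("rep1", "rep2", "rep3") if c in df.columns]
        grr_res = None
        if rep_cols:
            reps = [row.dropna().to_numpy(float) for _, row in df[rep_cols].iterrows()]
            if all(r.size >= 2 for r in reps):
                try:
                    grr_res = grr(reps)
                except DegenerateDataError as exc:
                    notes.append(f"GRR not applicable: {exc}")
            else:
                notes.append("GRR skipped: some samples have fewer than 2 replicates")

        per_species: Dict[str, Dict[str, float]] = {}
        diffs_by_species: Dict[str, np.ndarray] = {}
        for sp, sub in df.groupby("species", sort=True):
            xs = sub["reference_volume"].to_numpy(float)
            ys = sub["estimated_volume"].to_numpy(float)
            d = (ys - xs) if conv.diff_direction == "est_minus_obs" else (xs - ys)
            diffs_by_species[str(sp)] = d
            if len(sub) < 2:
                notes.append(f"species {sp!r} has a single sample; "
                             "kept in overall metrics, skipped per-species")
                continue
            m = regression_metrics(xs, ys)
            m.update({k: ba_sp[k] for ba_sp in [bland_altman(xs, ys, conv)]
                      for k in ("mean_diff", "sd_diff", "uloa", "lloa")})
            try:
                m["ccc"] = ccc(xs, ys, conv)
            except DegenerateDataError:
                m["ccc"] = None
            per_species[str(sp)] = m

        kw_res = None
        multi = {sp: d for sp, d in diffs_by_species.items() if d.size >= 2}
        if len(multi) >= 2:
            try:
                kw_res = kruskal_wallis(list(multi.values()), conv)
            except DegenerateDataError as exc:
                notes.append(f"Kruskal–Wallis not applicable: {exc}")

        pairwise: List[Dict[str, object]] = []
        species_list = sorted(multi)
        for a, b in combinations(species_list, 2):
            res = mann_whitney_u(multi[a], multi[b], conv)
            pairwise.append({"species_a": a, "species_b": b, **res})
        if pairwise:
            adj = holm_adjust([row["p"] for row in pairwise])
            for row, pa in zip(pairwise, adj):
                row["p_holm"] = pa

        return AgreementResults(
            model=self, n=len(df), overall=overall, bland_altman=ba, ccc=rho_c,
            grr=grr_res, per_species=per_species, kruskal_wallis=kw_res,
            pairwise=pairwise, conventions=conv, notes=notes)


@dataclass
class AgreementResults:
    """Fitted agreement statistics; see :meth:`summary` for a printable table."""

    model: VolumeAgreement
    n: int
    overall: Dict[str, float]
    bland_altman: Dict[str, object]
    ccc: Optional[float]
    grr: Optional[Dict[str, float]]
    per_species: Dict[str, Dict[str, float]]
    kruskal_wallis: Optional[Dict[str, float]]
    pairwise: List[Dict[str, object]]
    conventions: Conventions
    notes: List[str]

    def to_dict(self) -> dict:
        ba = {k: v for k, v in self.bland_altman.items()
              if k not in ("pair_means", "pair_diffs")}

        def _clean(d):
            if isinstance(d, dict):
                return {k: _clean(v) for k, v in d.items()}
            if isinstance(d, (np.floating, np.integer)):
                return d.item()
            return d

        return _clean({
            "schema_version": 1,
            "n": self.n,
            "conventions": asdict(self.conventions),
            "overall": self.overall,
            "bland_altman": ba,
            "ccc": self.ccc,
            "grr": self.grr,
            "per_species": self.per_species,
            "kruskal_wallis": self.kruskal_wallis,
            "pairwise_mann_whitney": self.pairwise,
            "notes": self.notes,
        })

    def summary(self) -> str:
        o, ba = self.overall, self.bland_altman
        lines = [
            "Volume agreement: TLS estimate vs reference (water displacement)",
            "=" * 66,
            f"n = {self.n}    difference = {self.conventions.diff_direction}"
            f"    CCC variances = {self.conventions.variance_mode}",
            "-" * 66,
            f"R²      {o['r_squared']:>10.4f}    RMSE   {o['rmse']:>10.2f} cm³",
            f"RE      {o['re']:>10.4f}    Bias   {o['bias']:>10.2f} cm³",
            f"rRMSE   {o['rrmse']:>9.2f}%",
            f"Bland–Altman: d̄ = {ba['mean_diff']:.2f} cm³, s = {ba['sd_diff']:.2f} cm³, "
            f"LoA [{ba['lloa']:.2f}, {ba['uloa']:.2f}] cm³",
        ]
        if self.ccc is not None:
            lines.append(f"CCC     {self.ccc:>10.4f}")
        if self.grr is not None:
            lines.append(f"GRR     {self.grr['grr_percent']:>9.2f}%  "
                         f"(repeatability {self.grr['var_repeatability']:.3g}, "
                         f"parts {self.grr['var_parts']:.3g})")
        if self.per_species:
            lines.append("-" * 66)
            lines.append(f"{'species':<24}{'n':>4}{'RMSE':>10}{'rRMSE %':>10}{'bias':>10}")
            for sp, m in self.per_species.items():
                lines.append(f"{sp:<24}{m['n']:>4}{m['rmse']:>10.2f}"
                             f"{m['rrmse']:>10.2f}{m['bias']:>10.2f}")
        if self.kruskal_wallis is not None:
            lines.append(f"Kruskal–Wallis (per-species differences): "
                         f"H = {self.kruskal_wallis['H']:.4f}, p = {self.kruskal_wallis['p']:.4g}")
        for row in self.pairwise:
            lines.append(f"  MWU {row['species_a']} vs {row['species_b']}: "
                         f"U = {row['U']:.1f}, p = {row['p']:.4g} (Holm {row['p_holm']:.4g})")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_bland_altman(self, ax=None):
        """Difference-vs-mean scatter with d̄ and the 95 % limits of agreement."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ba = self.bland_altman
        ax.scatter(ba["pair_means"], ba["pair_diffs"], s=12, alpha=0.7)
        for val, style in ((ba["mean_diff"], "-"), (ba["uloa"], "--"), (ba["lloa"], "--")):
            ax.axhline(val, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of methods (cm³)")
        ax.set_ylabel(f"difference, {self.conventions.diff_direction} (cm³)")
        return ax

    def plot_scatter(self, ax=None):
        """Estimated vs observed with the identity line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        x = df["reference_volume"]
        y = df["estimated_volume"]
        ax.scatter(x, y, s=12, alpha=0.7)
        lim = [0, max(x.max(), y.max()) * 1.05]
        ax.plot(lim, lim, "k--", linewidth=1, label="1:1")
        ax.set_xlabel("reference volume (cm³)")
        ax.set_ylabel("TLS estimated volume (cm³)")
        ax.legend()
        return ax


def build_report(samples: Union[pd.DataFrame, Sequence[DiscSample]],
                 conventions: Optional[Conventions] = None) -> AgreementResults:
    """Convenience wrapper: ``VolumeAgreement(samples, conventions).fit()``."""
    return VolumeAgreement(samples, conventions).fit()
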