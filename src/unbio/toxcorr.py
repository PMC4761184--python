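"""Rank correlation of Ub with toxicity, potency bands, hit rates, EC50s.

Toxicity enters on the log10 scale of the half-effect concentration (EC50
or LD50, molar; mammalian oral/IP doses as mol per kg body mass).  The
headline statistic is the rank correlation between a Ub measure and log10
EC50 per endpoint: a *negative* coefficient means larger Ub goes with lower
toxic concentration, i.e. a more potent toxin.  Significance tiers follow
the toxicology-table convention (* < 0.05, ** < 0.01, *** below the
Bonferroni family threshold alpha / (endpoints x measures)), and the
potency-band analysis recomputes the correlation inside round-log-unit
bands of EC50 with Fisher-z confidence intervals -- the low-potency bands
are where the Ub signal is expected to live.

Rank correlation is Spearman with average ranks for ties (Kendall is
available behind a flag); the two-sided p comes from the large-sample t
approximation, both via scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .molgraph import (
    ALKALI_METALS,
    HALOGENS,
    MolecularGraph,
    _NONMETALS,
    parse_components,
)

DEFAULT_TIERS = {"*": 0.05, "**": 0.01}  # *** threshold is computed


class CorrelationError(ValueError):
    """Raised when a correlation is undefined or under-determined."""


@dataclass(frozen=True)
class ToxicityRecord:
    """One (compound, endpoint) measurement on the log10 molar scale."""

    compound_id: str
    smiles: str
    endpoint: str
    log10_value: float
    unit: str = "M"  # "M" or "mol/kg" for mammalian whole-organism doses

    def __post_init__(self):
        if not math.isfinite(self.log10_value):
            raise ValueError("log10 half-effect value must be finite")


@dataclass(frozen=True)
class CorrelationResult:
    endpoint: str
    ub_n: int
    n: int
    rho: float
    p_value: float
    tier: str

    def __post_init__(self):
        if not (math.isnan(self.rho) or abs(self.rho) <= 1.0 + 1e-12):
            raise ValueError("|rho| must be <= 1")


@dataclass(frozen=True)
class PotencyBand:
    """Correlation within a half-open [lo, hi) band of log10 EC50."""

    lo: float  # -inf for the open lower extreme
    hi: float  # +inf for the open upper extreme
    n: int
    rho: float  # nan when n < 4 or undefined
    ci_lo: float
    ci_hi: float


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    Raises :class:`CorrelationError` for constant input, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise CorrelationError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CorrelationError("rank correlation of a constant vector is undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def kendall(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b, the alternative rank-correlation flavour."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise CorrelationError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CorrelationError("rank correlation of a constant vector is undefined")
    tau, p = stats.kendalltau(x, y)
    return float(tau), float(p)


def bonferroni_threshold(n_endpoints: int, n_measures: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / (endpoints x measures)."""
    if n_endpoints < 1 or n_measures < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_endpoints * n_measures)


def family_wise_prob(n_tests: int, alpha_star: float) -> float:
    """Chance of at least one false positive among independent tests at
    per-test level ``alpha_star``: 1 - (1 - alpha*)^n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 1.0 - (1.0 - alpha_star) ** n_tests


def fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if n < 4:
        raise CorrelationError("Fisher CI needs n >= 4")
    z = math.atanh(rho)
    half = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def significance_tier(
    p_value: float,
    star_threshold: float,
    tiers: dict[str, float] = DEFAULT_TIERS,
) -> str:
    """Assign '', '*', '**' or '***' from configured thresholds."""
    if p_value < star_threshold:
        return "***"
    if p_value < tiers["**"]:
        return "**"
    if p_value < tiers["*"]:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# endpoint correlation and potency bands
# ---------------------------------------------------------------------------


def _join(records: Sequence[ToxicityRecord], ub: pd.DataFrame, n: int) -> pd.DataFrame:
    col = f"ub{n}"
    if col not in ub.columns:
        raise KeyError(f"Ub table lacks column {col!r}")
    rec = pd.DataFrame(
        [(r.compound_id, r.log10_value) for r in records],
        columns=["id", "log10_value"],
    )
    merged = rec.merge(ub[["id", col]].dropna(), on="id", how="inner")
    return merged.sort_values("id", kind="stable").reset_index(drop=True)


def correlate_endpoint(
    records: Sequence[ToxicityRecord],
    ub: pd.DataFrame,
    n: int,
    endpoint: Optional[str] = None,
    alpha: float = 0.05,
    n_endpoints: int = 35,
    n_measures: int = 2,
    method: str = "spearman",
) -> CorrelationResult:
    """Rank correlation of Ub_n with log10 EC50 for one endpoint.

    Joins toxicity records to the Ub table on compound id; order of the
    input records does not affect the result.  Fewer than 4 matched
    compounds is a refusal, and a constant Ub column is flagged undefined.
    """
    endpoint = endpoint or (records[0].endpoint if records else "")
    merged = _join(records, ub, n)
    if len(merged) < 4:
        raise CorrelationError(
            f"endpoint {endpoint!r}: only {len(merged)} of {len(records)} "
            f"records joined to the Ub table; need >= 4"
        )
    corr = {"spearman": spearman, "kendall": kendall}[method]
    rho, p = corr(merged[f"ub{n}"].to_numpy(), merged["log10_value"].to_numpy())
    star = bonferroni_threshold(n_endpoints, n_measures, alpha)
    return CorrelationResult(
        endpoint=endpoint,
        ub_n=n,
        n=len(merged),
        rho=rho,
        p_value=p,
        tier=significance_tier(p, star),
    )


def band_analysis(
    records: Sequence[ToxicityRecord],
    ub: pd.DataFrame,
    n: int,
    edges: Sequence[float] = (-4.0, -3.0, -2.0),
    method: str = "spearman",
) -> list[PotencyBand]:
    """Per-band rank correlations over half-open log10 EC50 bands.

    ``edges`` gives the interior cut points; the extreme bands are open
    ended, so the bands partition the whole line.  Bands with fewer than 4
    compounds are reported with their count but an undefined correlation.
    """
    edges = list(edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("band edges must be strictly increasing")
    merged = _join(records, ub, n)
    bounds = [-math.inf] + edges + [math.inf]
    corr = {"spearman": spearman, "kendall": kendall}[method]
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mask = (merged["log10_value"] >= lo) & (merged["log10_value"] < hi)
        sub = merged[mask]
        if len(sub) >= 4:
            try:
                rho, _ = corr(sub[f"ub{n}"].to_numpy(), sub["log10_value"].to_numpy())
                ci_lo, ci_hi = fisher_ci(rho, len(sub))
            except CorrelationError:
                rho, ci_lo, ci_hi = math.nan, math.nan, math.nan
        else:
            rho, ci_lo, ci_hi = math.nan, math.nan, math.nan
        out.append(PotencyBand(lo, hi, int(len(sub)), rho, ci_lo, ci_hi))
    return out


def correlation_table(
    grouped_records: dict[str, Sequence[ToxicityRecord]],
    ub: pd.DataFrame,
    ns: Sequence[int] = (5, 6),
    **kwargs,
) -> pd.DataFrame:
    """Endpoint-by-Ub summary table (one row per endpoint)."""
    rows = []
    for endpoint, records in grouped_records.items():
        row: dict = {"endpoint": endpoint}
        for n in ns:
            try:
                res = correlate_endpoint(records, ub, n, endpoint=endpoint, **kwargs)
                row[f"n"] = res.n
                row[f"rho_ub{n}"] = res.rho
                row[f"p_ub{n}"] = res.p_value
                row[f"tier_ub{n}"] = res.tier
            except CorrelationError as exc:
                row[f"rho_ub{n}"] = math.nan
                row[f"tier_ub{n}"] = f"undefined: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hit-rate curve
# ---------------------------------------------------------------------------


def hit_rate_curve(
    tests: Sequence[tuple[str, float, bool]],
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Fraction of tested compounds active per log10-concentration bin.

    ``tests`` are (compound, concentration, active) observations; each bin
    is half-open ``[k*w, (k+1)*w)`` on the log10 scale and only compounds
    actually tested in a bin enter its denominator.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for compound, conc, active in tests:
        if conc <= 0:
            raise ValueError(f"non-positive concentration for {compound!r}")
        logc = math.log10(conc)
        rows.append((math.floor(logc / bin_width), bool(active)))
    df = pd.DataFrame(rows, columns=["bin_index", "active"])
    grouped = df.groupby("bin_index")["active"].agg(["sum", "count"]).reset_index()
    grouped["log10_conc_lo"] = grouped["bin_index"] * bin_width
    grouped["hit_rate"] = grouped["sum"] / grouped["count"]
    return grouped.rename(columns={"sum": "n_active", "count": "n_tested"})[
        ["log10_conc_lo", "n_active", "n_tested", "hit_rate"]
    ]


# ---------------------------------------------------------------------------
# yeast EC50 pipeline
# ---------------------------------------------------------------------------


def ec50_from_curve(
    concentrations: Sequence[float], inhibition: Sequence[float]
) -> Optional[float]:
    """EC50 by log-linear interpolation at the first 50% crossing.

    ``concentrations`` must be strictly increasing and positive; inhibition
    is in percent (assay noise outside [0, 100] is tolerated).  Returns the
    tested concentration when it hits exactly 50%, and ``None`` when the
    curve never crosses 50% within the tested range (which drives the
    <50%-at-max / >50%-at-min exclusion filters).
    """
    conc = list(concentrations)
    inh = list(inhibition)
    if len(conc) != len(inh) or len(conc) < 2:
        raise ValueError("need >= 2 paired (concentration, inhibition) points")
    if any(c <= 0 for c in conc) or any(b <= a for a, b in zip(conc, conc[1:])):
        raise ValueError("concentrations must be positive and strictly increasing")
    for c, y in zip(conc, inh):
        if y == 50.0:
            return c
    for (c0, y0), (c1, y1) in zip(zip(conc, inh), zip(conc[1:], inh[1:])):
        if y0 < 50.0 <= y1:
            t = (50.0 - y0) / (y1 - y0)
            return 10 ** (math.log10(c0) + t * (math.log10(c1) - math.log10(c0)))
    return None


_METALS = frozenset  # see molgraph._NONMETALS


def _classify_structure(smiles: str) -> tuple[str, Optional[str]]:
    """('ok'|'organometallic'|'mixture', reason) for a raw structure.

    Organometallic: any carbon-metal bond.  Mixtures/salts are allowed only
    when every component besides the largest organic one is a bare halide
    or alkali-metal counter-ion.
    """
    comps = parse_components(smiles)
    for comp in comps:
        for bond in comp.GetBonds():
            syms = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
            metals = {s for s in syms if s not in _NONMETALS}
            if metals and "C" in syms:
                return "organometallic", f"C-{sorted(metals)[0]} bond"
    if len(comps) > 1:
        organic = [c for c in comps if any(a.GetSymbol() == "C" for a in c.GetAtoms())]
        if len(organic) != 1:
            return "mixture", "not a single organic component"
        for comp in comps:
            if comp is organic[0]:
                continue
            if comp.GetNumAtoms() != 1:
                return "mixture", "polyatomic counter-ion"
            sym = comp.GetAtomWithIdx(0).GetSymbol()
            if sym not in HALOGENS | ALKALI_METALS:
                return "mixture", f"disallowed counter-ion {sym}"
    return "ok", None


def yeast_filter(
    matrix: pd.DataFrame,
    structures: dict[str, str],
    spread_limit: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Growth-inhibition matrix -> filtered per-compound mean EC50 table.

    ``matrix`` is long format with columns ``id, strain, concentration_M,
    pct_inhibition``; ``structures`` maps compound id to SMILES.  Exclusion
    rules, applied in order, with every exclusion logged rather than raised:

    1. organometallic compounds (carbon-metal bond);
    2. mixtures/salts other than halide or alkali-metal salts (allowed
       salts are scored on the organic component);
    3. mean growth inhibition across strains < 50% at the highest tested
       concentration, or > 50% at the lowest;
    4. per-strain EC50s (log-linear interpolation) whose spread
       (max - min) / mean exceeds ``spread_limit``.

    Returns ``(ec50_table, exclusion_log)``; the table has one row per
    retained compound with its mean EC50 (molar) and the SMILES actually
    scored.
    """
    required = {"id", "strain", "concentration_M", "pct_inhibition"}
    if not required <= set(matrix.columns):
        raise ValueError(f"matrix needs columns {sorted(required)}")
    kept_rows, log_rows = [], []

    def exclude(cid: str, rule: str, detail: str) -> None:
        log_rows.append({"id": cid, "rule": rule, "detail": detail})

    for cid, group in matrix.groupby("id", sort=True):
        smiles = structures.get(str(cid))
        if smiles is None:
            exclude(cid, "no structure", "id missing from structure table")
            continue
        kind, reason = _classify_structure(smiles)
        if kind == "organometallic":
            exclude(cid, "organometallic", reason or "")
            continue
        if kind == "mixture":
            exclude(cid, "mixture/salt", reason or "")
            continue
        from .molgraph import largest_organic_component

        scored = largest_organic_component(smiles)
        mean_curve = (
            group.groupby("concentration_M")["pct_inhibition"].mean().sort_index()
        )
        concs = mean_curve.index.to_numpy()
        if mean_curve.iloc[-1] < 50.0:
            exclude(cid, "max<50%", f"{mean_curve.iloc[-1]:.1f}% at top concentration")
            continue
        if mean_curve.iloc[0] > 50.0:
            exclude(cid, "min>50%", f"{mean_curve.iloc[0]:.1f}% at lowest concentration")
            continue
        ec50s = []
        for strain, sg in group.groupby("strain"):
            sg = sg.sort_values("concentration_M")
            ec = ec50_from_curve(
                sg["concentration_M"].to_numpy(), sg["pct_inhibition"].to_numpy()
            )
            if ec is not None:
                ec50s.append(ec)
        if not ec50s:
            exclude(cid, "no crossing", "no strain curve crosses 50%")
            continue
        spread = (max(ec50s) - min(ec50s)) / (sum(ec50s) / len(ec50s))
        if spread > spread_limit:
            exclude(cid, "strain spread", f"(max-min)/mean = {spread:.2f}")
            continue
        kept_rows.append(
            {
                "id": cid,
                "smiles": scored.canonical,
                "n_strains": len(ec50s),
                "ec50_M": sum(ec50s) / len(ec50s),
                "log10_ec50": math.log10(sum(ec50s) / len(ec50s)),
            }
        )
    return pd.DataFrame(kept_rows), pd.DataFrame(log_rows)
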