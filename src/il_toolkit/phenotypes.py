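"""Multi-location trait analysis for IL libraries.

Implements the analysis chain used to declare QTLs from an IL trial:
derived traits, per-location summaries, two-way ANOVA (location, genotype,
interaction), Dunnett many-to-one contrasts of every IL against the
recurrent-parent control, percent-of-control effect sizes, Pearson
correlation matrices, and the cross-location QTL-calling rule (an effect
is declared only when significant in at least two locations).

Dunnett adjustment
------------------
With k ILs compared to one control from a pooled-variance model, the
statistics T_i = (ybar_i - ybar_0) / (s * sqrt(1/n_i + 1/n_0)) follow an
equicorrelated multivariate t under the global null, with correlations
rho_ij = lambda_i * lambda_j and lambda_i = sqrt(n_i / (n_i + n_0)).  The
two-sided familywise-adjusted p-value 1 - P(max_i |T_i| <= |t|) is
evaluated by deterministic 2-D quadrature: Gauss-Hermite over the shared
control variate Z_0 and Gauss-Legendre over the pooled-SD chi variable
(chi_nu / sqrt(nu)), accurate to well below 1e-6 in absolute terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr

from .model import ValidationError

__all__ = [
    "derive_shape",
    "two_way_anova",
    "dunnett_test",
    "dunnett_adjusted_p",
    "call_qtls",
    "correlation_matrix",
    "location_summary",
    "AnovaResult",
    "DunnettResult",
    "QTLCall",
    "CorrelationResult",
]


def derive_shape(fl, fd):
    """Fruit shape FS = FL / FD (length over diameter).  FD must be > 0."""
    fl_a = np.asarray(fl, dtype=float)
    fd_a = np.asarray(fd, dtype=float)
    if np.any(fd_a <= 0):
        raise ValidationError("FD must be > 0 to derive FS = FL/FD")
    out = fl_a / fd_a
    if np.isscalar(fl) or (out.ndim == 0):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Dunnett many-to-one contrasts
# ---------------------------------------------------------------------------

_GH_NODES = 96
_GL_NODES = 128


@lru_cache(maxsize=None)
def _gh() -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    # E_Z[g(Z)] for Z ~ N(0,1): sum w_j g(sqrt(2) x_j) / sqrt(pi)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


@lru_cache(maxsize=None)
def _chi_nodes(df: int) -> tuple[np.ndarray, np.ndarray]:
    # S = chi_df / sqrt(df); integrate against its density on central mass
    chi = sps.chi(df)
    lo = chi.ppf(1e-12) / np.sqrt(df)
    hi = chi.ppf(1.0 - 1e-12) / np.sqrt(df)
    x, w = np.polynomial.legendre.leggauss(_GL_NODES)
    s = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    dens = chi.pdf(s * np.sqrt(df)) * np.sqrt(df)
    return s, w * 0.5 * (hi - lo) * dens


def _prob_max_abs_le(q: float, lambdas: np.ndarray, df: int) -> float:
    """P(max_i |T_i| <= q) for the equicorrelated Dunnett distribution."""
    if q <= 0:
        return 0.0
    z, wz = _gh()
    s, ws = _chi_nodes(df)
    lam = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lam**2)
    # grid dims: (s, z, k)
    qs = q * s[:, None, None]
    lz = lam[None, None, :] * z[None, :, None]
    inner = ndtr((qs - lz) / c) - ndtr((-qs - lz) / c)
    prod = np.prod(inner, axis=2)
    return float(ws @ prod @ wz)


def dunnett_adjusted_p(
    t_obs: float, lambdas: Sequence[float], df: int
) -> float:
    """Two-sided familywise-adjusted p for one observed Dunnett statistic."""
    p = 1.0 - _prob_max_abs_le(abs(float(t_obs)), np.asarray(lambdas), int(df))
    return min(1.0, max(0.0, p))


@dataclass
class DunnettResult:
    """Per-location Dunnett contrasts of each IL against the control.

    ``table`` is indexed by IL with columns n, mean, diff, t, p_unadjusted,
    p_adjusted and percent_diff (= 100 * (mean_i - mean_0) / mean_0, the
    percent-of-control effect convention).
    """

    location: str | None
    trait: str
    control: str
    control_mean: float
    control_n: int
    df: int
    pooled_sd: float
    table: pd.DataFrame


def dunnett_test(
    pheno: pd.DataFrame,
    trait: str,
    control: str,
    location: str | None = None,
) -> DunnettResult:
    """Two-sided Dunnett contrasts of every IL mean against the control.

    Uses the pooled within-group variance over all groups (N - g residual
    df).  ``pheno`` is a long-format table; pass ``location`` to restrict
    to a single trial.
    """
    d = pheno[pheno["trait"] == trait]
    if location is not None:
        d = d[d["location"] == location]
    d = d.dropna(subset=["value"])
    if control not in set(d["line"]):
        raise ValidationError(
            f"control line {control!r} has no records for trait {trait!r}"
            + (f" at {location!r}" if location else "")
        )
    groups = {line: g["value"].to_numpy(float) for line, g in d.groupby("line")}
    y0 = groups.pop(control)
    if len(y0) < 2:
        raise ValidationError("control needs >= 2 replicates")
    if not groups:
        raise ValidationError("no IL groups to compare against the control")
    il_ids = sorted(groups)
    ns = np.array([len(groups[i]) for i in il_ids])
    n0 = len(y0)
    N = int(ns.sum()) + n0
    g = len(il_ids) + 1
    df = N - g
    if df < 1:
        raise ValidationError("no residual degrees of freedom for pooled variance")
    ss = sum(
        float(((v - v.mean()) ** 2).sum()) for v in [y0, *groups.values()]
    )
    if ss <= 0:
        raise ValidationError("zero pooled variance: all groups are constant")
    s2 = ss / df
    s = np.sqrt(s2)
    mean0 = float(y0.mean())
    means = np.array([groups[i].mean() for i in il_ids])
    diffs = means - mean0
    se = s * np.sqrt(1.0 / ns + 1.0 / n0)
    t = diffs / se
    lambdas = np.sqrt(ns / (ns + n0))
    p_unadj = 2.0 * sps.t.sf(np.abs(t), df)
    p_adj = np.array(
        [dunnett_adjusted_p(ti, lambdas, df) for ti in t]
    )
    p_adj = np.maximum(p_adj, p_unadj)  # monotonicity can't be beaten by quadrature
    pct = 100.0 * diffs / mean0
    table = pd.DataFrame(
        {
            "n": ns,
            "mean": means,
            "diff": diffs,
            "t": t,
            "p_unadjusted": p_unadj,
            "p_adjusted": np.minimum(p_adj, 1.0),
            "percent_diff": pct,
        },
        index=pd.Index(il_ids, name="line"),
    )
    return DunnettResult(
        location=location,
        trait=trait,
        control=control,
        control_mean=mean0,
        control_n=n0,
        df=df,
        pooled_sd=float(s),
        table=table,
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Type III two-way ANOVA of one trait.

    ``table`` has rows location, line, location:line and Residual with
    columns df, sum_sq, F and p; ``label`` is e.g. "3L" or "2L" for the
    number of locations analysed.
    """

    trait: str
    label: str
    n_locations: int
    table: pd.DataFrame


def two_way_anova(
    pheno: pd.DataFrame,
    trait: str,
    locations: Sequence[str] | None = None,
    include_block: bool = False,
    ss_type: int = 3,
) -> AnovaResult:
    """Two-way ANOVA: value ~ location + line + location:line.

    Least-squares fit with sum-to-zero factor coding and Type III sums of
    squares by default (Type II via ``ss_type=2``).  With a single
    location the layout degenerates to a one-way genotype ANOVA.  Empty
    location x line cells are a rank-deficiency error naming the cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = pheno[pheno["trait"] == trait].dropna(subset=["value"]).copy()
    if locations is not None:
        d = d[d["location"].isin(list(locations))]
    if d.empty:
        raise ValidationError(f"no records for trait {trait!r}")
    d["value"] = d["value"].astype(float)
    n_loc = d["location"].nunique()
    if d["line"].nunique() < 2:
        raise ValidationError("two-way ANOVA needs >= 2 genotypes")

    if n_loc >= 2:
        cells = d.groupby(["location", "line"]).size().unstack(fill_value=0)
        empty = [
            (loc, line)
            for loc in cells.index
            for line in cells.columns
            if cells.loc[loc, line] == 0
        ]
        if empty:
            raise ValidationError(
                f"empty location x line cells (rank deficient): {empty[:10]}"
            )
        formula = "value ~ C(location, Sum) * C(line, Sum)"
    else:
        formula = "value ~ C(line, Sum)"
    if include_block:
        formula += " + C(block, Sum)"

    model = smf.ols(formula, data=d).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    rename = {
        "C(location, Sum)": "location",
        "C(line, Sum)": "line",
        "C(location, Sum):C(line, Sum)": "location:line",
        "C(block, Sum)": "block",
    }
    aov = aov.rename(index=rename)
    if "Intercept" in aov.index:
        aov = aov.drop(index="Intercept")
    aov = aov.rename(columns={"PR(>F)": "p"})
    aov["df"] = aov["df"].astype(int)
    aov = aov[["df", "sum_sq", "F", "p"]]
    return AnovaResult(trait=trait, label=f"{n_loc}L", n_locations=n_loc, table=aov)


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------


@dataclass
class QTLCall:
    """Cross-location decision for one (IL, trait) pair."""

    il: str
    trait: str
    per_location_significant: dict[str, bool]
    per_location_percent: dict[str, float]
    n_significant: int
    called: bool
    direction: int  # sign of the mean percent effect (0 if exactly zero)
    mean_percent: float


def call_qtls(
    results_by_location: Mapping[str, DunnettResult],
    alpha: float = 0.05,
    min_locations: int = 2,
    require_concordant: bool = True,
) -> list[QTLCall]:
    """Apply the >=2-location rule to per-location Dunnett results.

    An IL is called for the trait iff its adjusted p < ``alpha`` in at
    least ``min_locations`` locations and (by default) the percent effects
    at those significant locations agree in sign — a QTL flipping sign
    across locations is an interaction, not a main effect.
    """
    if len(results_by_location) < 2:
        raise ValidationError("QTL calling needs results from >= 2 locations")
    traits = {r.trait for r in results_by_location.values()}
    if len(traits) != 1:
        raise ValidationError(f"mixed traits in results: {sorted(traits)}")
    trait = traits.pop()
    ils: set[str] = set()
    for r in results_by_location.values():
        ils.update(r.table.index)
    calls: list[QTLCall] = []
    for il in sorted(ils):
        sig: dict[str, bool] = {}
        pct: dict[str, float] = {}
        for loc in sorted(results_by_location):
            r = results_by_location[loc]
            if il in r.table.index:
                sig[loc] = bool(r.table.loc[il, "p_adjusted"] < alpha)
                pct[loc] = float(r.table.loc[il, "percent_diff"])
        n_sig = sum(sig.values())
        called = n_sig >= min_locations
        if called and require_concordant:
            signs = {np.sign(pct[loc]) for loc, s in sig.items() if s}
            called = len(signs) == 1 and 0.0 not in signs
        mean_pct = float(np.mean(list(pct.values()))) if pct else float("nan")
        calls.append(
            QTLCall(
                il=il,
                trait=trait,
                per_location_significant=sig,
                per_location_percent=pct,
                n_significant=n_sig,
                called=called,
                direction=int(np.sign(mean_pct)) if np.isfinite(mean_pct) else 0,
                mean_percent=mean_pct,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Correlations and summaries
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Pearson correlations among traits at one location (fruit level)."""

    location: str
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def correlation_matrix(
    pheno: pd.DataFrame,
    traits: Sequence[str] | None = None,
    alpha: float = 0.01,
) -> dict[str, CorrelationResult]:
    """Per-location Pearson correlation matrices on fruit-level records.

    Missing values are handled by pairwise-complete deletion; pairs with
    fewer than 3 complete records, or a constant trait, yield NA.
    """
    out: dict[str, CorrelationResult] = {}
    for loc in sorted(pheno["location"].unique()):
        d = pheno[pheno["location"] == loc]
        wide = d.pivot_table(
            index=["block", "line", "replicate"],
            columns="trait",
            values="value",
            aggfunc="first",
        )
        use = list(traits) if traits is not None else sorted(wide.columns)
        use = [t for t in use if t in wide.columns]
        k = len(use)
        r = pd.DataFrame(np.full((k, k), np.nan), index=use, columns=use)
        p = r.copy()
        for i, a in enumerate(use):
            for j, b in enumerate(use):
                if j < i:
                    continue
                pair = wide[[a, b]].dropna() if a != b else wide[[a]].dropna()
                if a == b:
                    if len(pair) >= 1 and pair[a].nunique() > 1:
                        r.loc[a, b] = 1.0
                        p.loc[a, b] = 0.0
                    continue
                if len(pair) < 3:
                    continue
                x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue  # constant trait: r undefined
                res = sps.pearsonr(x, y)
                r.loc[a, b] = r.loc[b, a] = res.statistic
                p.loc[a, b] = p.loc[b, a] = res.pvalue
        sig = (p < alpha) & p.notna()
        out[loc] = CorrelationResult(loc, r, p, sig, alpha)
    return out


def location_summary(
    pheno: pd.DataFrame, line: str, trait: str
) -> pd.DataFrame:
    """Per-location mean, sample SD (n-1 denominator) and count for a line.

    The SD of a single record is reported as NA.
    """
    d = pheno[(pheno["line"] == line) & (pheno["trait"] == trait)].dropna(
        subset=["value"]
    )
    if d.empty:
        raise ValidationError(
            f"no records for line {line!r}, trait {trait!r}"
        )
    g = d.groupby("location")["value"]
    return pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()}
    )
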