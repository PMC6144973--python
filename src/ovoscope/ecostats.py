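"""The statistical stage: log traits, correlation PCA, mixed-model selection.

Seven per-egg trait variables (spot number, mean spot size, spottiness,
background and spot reflectance in VIS and UV) are natural-log
transformed, reduced to two principal components of their correlation
matrix, and each component is modelled with site random intercepts under
competing fixed-effect structures: a spatio-temporal set (collection year,
latitude as linear term or penalized smooth) and an environmental set
(year, surface-to-volume ratio, insolation and temperature as smooths or
centered raw polynomials).  Candidate models are compared by AICc — REML
for the with/without-random-effect assessment, ML for fixed-effect
structures — with Akaike weights, marginal/conditional R^2 and a
competitive flag for models within 2 AICc of the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ovoscope._lmm import (
    MixedModelFit,
    RandomBlock,
    aicc,
    concurvity,
    fit_mixed,
    r2_nakagawa,
    smooth_design,
)
from ovoscope.spotscan import TRAIT_ORDER

__all__ = [
    "TRAIT_ORDER",
    "PCAResult",
    "ModelComparison",
    "log_traits",
    "pca_corr",
    "fit_lmm",
    "fit_smooth_term",
    "fit_model",
    "aicc",
    "akaike_weights",
    "compare",
    "r2_nakagawa",
    "concurvity",
    "run_selection",
    "MixedModelFit",
]

REQUIRED_COVARIATES = (
    "site",
    "latitude",
    "longitude",
    "year",
    "insolation",
    "temperature",
    "sv",
)


# --------------------------------------------------------------------------
# trait transformation and PCA
# --------------------------------------------------------------------------


def log_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform the seven trait columns.

    Spot number uses log(x + 1) so spotless eggs stay admissible; an egg
    with zero spottiness cannot be log-transformed in the area traits and
    is marked in an ``incomplete`` flag column (excluded from the PCA)
    rather than silently dropped.
    """
    out = table.copy()
    missing = [c for c in TRAIT_ORDER if c not in out.columns]
    if missing:
        raise KeyError(f"trait columns missing: {missing}")
    vals = out[list(TRAIT_ORDER)].to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("trait values must be non-negative")
    zero_area = (out["spottiness"].to_numpy(dtype=float) == 0) | np.isnan(
        out[["spot_size", "spottiness", "s_vis", "s_uv"]].to_numpy(float)
    ).any(axis=1)
    out["spot_number"] = np.log1p(out["spot_number"].astype(float))
    for col in TRAIT_ORDER[1:]:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[col] = np.log(out[col].astype(float))
    out["incomplete"] = zero_area
    return out


def check_loadings(v1: np.ndarray, v2: np.ndarray, tol: float = 0.01
                   ) -> dict[str, float]:
    """Unit-norm and orthogonality diagnostics for two loading vectors.

    Returns the deviations {|1 - ||v1|||, |1 - ||v2|||, |v1 . v2|}; a pair
    of valid eigenvectors of a correlation matrix keeps all three below
    ``tol``.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    res = {
        "norm_dev_1": abs(1.0 - float(np.linalg.norm(v1))),
        "norm_dev_2": abs(1.0 - float(np.linalg.norm(v2))),
        "abs_dot": abs(float(v1 @ v2)),
    }
    res["ok"] = float(all(v < tol for v in res.values()))
    return res


@dataclass
class PCAResult:
    """Eigen-decomposition of the trait correlation matrix."""

    loadings: np.ndarray  # (7, n_components), unit columns
    eigenvalues: np.ndarray  # all 7
    variance_fractions: np.ndarray  # all 7, sums to 1
    scores: np.ndarray  # (n, n_components)
    variables: tuple[str, ...] = TRAIT_ORDER
    sign_flipped: tuple[bool, ...] = ()

    def validate(self, tol: float = 1e-8) -> None:
        for j in range(self.loadings.shape[1]):
            if abs(1 - np.linalg.norm(self.loadings[:, j])) > tol:
                raise ValueError(f"loading column {j} is not unit norm")
        gram = self.loadings.T @ self.loadings
        off = gram - np.diag(np.diag(gram))
        if np.abs(off).max() > tol:
            raise ValueError("loading columns are not orthogonal")

    check_loadings = staticmethod(check_loadings)


def pca_corr(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of the correlation matrix of the 7 log traits.

    Sign convention: PC1 is oriented so the VIS background-reflectance
    loading is positive (positive scores = lighter eggs), PC2 so the
    spot-size loading is positive (positive scores = fewer, larger spots).
    """
    if "incomplete" in table.columns:
        table = table.loc[~table["incomplete"].astype(bool)]
    data = table[list(TRAIT_ORDER)].to_numpy(dtype=float)
    data = data[~np.isnan(data).any(axis=1)]
    if len(data) < 8:
        raise ValueError("need at least 8 complete rows for the PCA")
    sds = data.std(axis=0, ddof=1)
    tiny = sds <= 1e-10 * np.maximum(1.0, np.abs(data).max(axis=0))
    if tiny.any():
        bad = [v for v, t in zip(TRAIT_ORDER, tiny) if t]
        raise ValueError(f"constant trait columns: {bad}")
    corr = np.corrcoef(data, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    flips = []
    anchor = {0: TRAIT_ORDER.index("b_vis"), 1: TRAIT_ORDER.index("spot_size")}
    for j in range(vecs.shape[1]):
        a = anchor.get(j)
        flip = a is not None and vecs[a, j] < 0
        if flip:
            vecs[:, j] = -vecs[:, j]
        flips.append(flip)

    std_data = (data - data.mean(axis=0)) / sds
    scores = std_data @ vecs[:, :n_components]
    return PCAResult(
        loadings=vecs[:, :n_components],
        eigenvalues=vals,
        variance_fractions=vals / vals.sum(),
        scores=scores,
        sign_flipped=tuple(flips),
    )


# --------------------------------------------------------------------------
# model fitting wrappers
# --------------------------------------------------------------------------


def _site_block(site_ids: np.ndarray) -> RandomBlock:
    sites, inv = np.unique(np.asarray(site_ids), return_inverse=True)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a site random effect")
    Z = np.zeros((len(inv), len(sites)))
    Z[np.arange(len(inv)), inv] = 1.0
    return RandomBlock("site", Z)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    site_ids: np.ndarray | None,
    criterion: str = "ML",
    **kw,
) -> MixedModelFit:
    """Random-intercept linear mixed model (site intercepts optional)."""
    blocks = [_site_block(site_ids)] if site_ids is not None else []
    return fit_mixed(y, X, blocks, criterion=criterion, **kw)


Term = tuple  # ("linear", col) | ("poly", col, degree) | ("smooth", col)


def build_design(
    data: pd.DataFrame, terms: list[Term]
) -> tuple[np.ndarray, list[RandomBlock], list[str], dict[str, list[int]]]:
    """Design matrix, smooth random blocks, names and per-term columns.

    Polynomial terms use centered, unit-SD covariates raised to powers
    1..degree (raw, not orthogonal — coefficients are on the standardized
    scale).  Smooth terms contribute their linear null space to X and
    their penalized wiggle as a random block.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    blocks: list[RandomBlock] = []
    contrib: dict[str, list[int]] = {}
    for term in terms:
        kind, col = term[0], term[1]
        x = data[col].to_numpy(dtype=float)
        if kind == "linear":
            cols.append(x)
            names.append(col)
            contrib[col] = [len(cols) - 1]
        elif kind == "poly":
            degree = int(term[2])
            z = (x - x.mean()) / x.std()
            idxs = []
            for d in range(1, degree + 1):
                cols.append(z**d)
                names.append(f"{col}^{d}" if d > 1 else col)
                idxs.append(len(cols) - 1)
            contrib[col] = idxs
        elif kind == "smooth":
            x_lin, Z = smooth_design(x)
            cols.append(x_lin[:, 0])
            names.append(f"{col}(lin)")
            contrib[col] = [len(cols) - 1]
            blocks.append(RandomBlock(col, Z, is_smooth=True))
        else:
            raise ValueError(f"unknown term kind {kind!r}")
    return np.column_stack(cols), blocks, names, contrib


def fit_model(
    data: pd.DataFrame,
    response: str,
    terms: list[Term],
    site: bool = True,
    criterion: str = "ML",
    label: str = "",
) -> MixedModelFit:
    """Fit one candidate model described by a term list."""
    y = data[response].to_numpy(dtype=float)
    X, blocks, names, contrib = build_design(data, terms)
    if site:
        blocks = [_site_block(data["site"].to_numpy())] + blocks
    return fit_mixed(
        y, X, blocks, criterion=criterion, response=response,
        design=label or " + ".join(n for n in names if n != "intercept")
        or "null", term_names=names, contribution_cols=contrib,
    )


def fit_smooth_term(
    y: np.ndarray,
    covariate: np.ndarray,
    site_ids: np.ndarray | None = None,
    max_knots: int = 5,
    criterion: str = "ML",
) -> MixedModelFit:
    """Intercept + penalized cubic-spline smooth of one covariate.

    The basis dimension is capped at ``max_knots`` (5 by default, guarding
    against over-fitting); the smoothing parameter is estimated by the
    same profiled-likelihood machinery as the site variance.
    """
    if len(y) < 20:
        raise ValueError("need at least 20 observations for a smooth")
    x_lin, Z = smooth_design(np.asarray(covariate, float), n_basis=max_knots)
    X = np.column_stack([np.ones(len(y)), x_lin[:, 0]])
    blocks = [RandomBlock("s(x)", Z, is_smooth=True)]
    if site_ids is not None:
        blocks.insert(0, _site_block(site_ids))
    return fit_mixed(
        y, X, blocks, criterion=criterion,
        term_names=["intercept", "s(x)(lin)"],
        contribution_cols={"s(x)": [1]},
    )


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------


def akaike_weights(delta_aicc: np.ndarray) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    d = np.asarray(delta_aicc, dtype=float)
    rel = np.exp(-0.5 * (d - d.min()))
    return rel / rel.sum()


@dataclass
class ModelComparison:
    """Per-model AICc bookkeeping, the machine form of a selection table."""

    table: pd.DataFrame
    fits: list[MixedModelFit] = field(default_factory=list, repr=False)

    @property
    def best_label(self) -> str:
        return str(self.table.loc[self.table["delta_aicc"].idxmin(), "model"])

    @property
    def selected_label(self) -> str:
        """The model the selection procedure reports.

        Models within 2 AICc of the best are competitive, but a
        competitive model whose extra parameters do not explain enough
        variation to beat a simpler rival by more than 2 AICc is read as
        uninformative; the procedure therefore settles on the most
        parsimonious competitive model (fewest parameters, ties broken by
        AICc).  Nothing is pruned from the table itself.
        """
        comp = self.table.loc[self.table["competitive"]]
        comp = comp.sort_values(["df", "aicc"])
        return str(comp["model"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare(
    fits: list[MixedModelFit], labels: list[str] | None = None
) -> ModelComparison:
    """AICc, delta, Akaike weight and R^2 table for a set of fits.

    All fits must share the response and the fitting criterion; mixing ML
    and REML in one comparison is refused.  R^2 values are reported for
    parametric models only (smooth fits show NaN, printed as a dash).
    """
    if not fits:
        raise ValueError("no models to compare")
    crits = {f.criterion for f in fits}
    if len(crits) > 1:
        raise ValueError(f"cannot mix criteria in one comparison: {crits}")
    resp = {f.response for f in fits}
    if len(resp) > 1:
        raise ValueError(f"fits have different responses: {resp}")
    labels = labels or [f.design for f in fits]
    aiccs = np.array([aicc(f.loglik, f.k, f.n) for f in fits])
    delta = aiccs - aiccs.min()
    w = akaike_weights(delta)
    r2m, r2c = [], []
    for f in fits:
        if f.smooth_terms:
            r2m.append(np.nan)
            r2c.append(np.nan)
        else:
            m, c = r2_nakagawa(f)
            r2m.append(m)
            r2c.append(c)
    best = int(np.argmin(delta))
    best_terms = set(labels[best].lower().replace("+", " ").split())
    rows = pd.DataFrame(
        {
            "model": labels,
            "df": [f.k for f in fits],
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": w,
            "r2m": r2m,
            "r2c": r2c,
            "best": delta == 0,
            "competitive": delta <= 2.0,
            # competitive superset of the best model: its extra terms are
            # candidates for the uninformative-parameter reading
            "uninformative_extra": [
                bool(
                    0 < d <= 2.0
                    and best_terms
                    <= set(lbl.lower().replace("+", " ").split())
                )
                for d, lbl in zip(delta, labels)
            ],
        }
    )
    return ModelComparison(table=rows, fits=list(fits))


# --------------------------------------------------------------------------
# the full selection workflow
# --------------------------------------------------------------------------

SPATIO_TEMPORAL_SET: list[tuple[str, list[Term]]] = [
    ("Year + s(latitude)", [("linear", "year"), ("smooth", "latitude")]),
    ("Year + latitude", [("linear", "year"), ("linear", "latitude")]),
    ("Latitude", [("linear", "latitude")]),
    ("Year", [("linear", "year")]),
    ("Null model", []),
]

ENVIRONMENTAL_SET_FULL: list[tuple[str, list[Term]]] = [
    (
        "Year + sv + s(insolation) + s(temperature)",
        [("linear", "year"), ("linear", "sv"), ("smooth", "insolation"),
         ("smooth", "temperature")],
    ),
    (
        "Year + s(insolation) + s(temperature)",
        [("linear", "year"), ("smooth", "insolation"),
         ("smooth", "temperature")],
    ),
    (
        "Sv + s(insolation) + s(temperature)",
        [("linear", "sv"), ("smooth", "insolation"),
         ("smooth", "temperature")],
    ),
    (
        "Year + sv + s(insolation)",
        [("linear", "year"), ("linear", "sv"), ("smooth", "insolation")],
    ),
    (
        "Year + sv + s(temperature)",
        [("linear", "year"), ("linear", "sv"), ("smooth", "temperature")],
    ),
    (
        "Year + sv + insolation^3",
        [("linear", "year"), ("linear", "sv"), ("poly", "insolation", 3)],
    ),
    (
        "Year + sv + insolation^4",
        [("linear", "year"), ("linear", "sv"), ("poly", "insolation", 4)],
    ),
    ("Null model", []),
]

ENVIRONMENTAL_SET_NULLISH: list[tuple[str, list[Term]]] = [
    (
        "s(insolation) + s(temperature)",
        [("smooth", "insolation"), ("smooth", "temperature")],
    ),
    ("s(insolation)", [("smooth", "insolation")]),
    ("s(temperature)", [("smooth", "temperature")]),
    ("Insolation", [("linear", "insolation")]),
    ("Temperature", [("linear", "temperature")]),
    ("Null model", []),
]


def run_selection(table: pd.DataFrame, response: str) -> dict:
    """Full selection workflow for one response axis.

    Steps, in the order of the analysis: (i) REML AICc assessment of the
    site random intercept under the full parametric fixed model
    (year + latitude); (ii) ML AICc comparison of the spatio-temporal
    candidate set; (iii) ML AICc comparison of the environmental set —
    the variant including year and surface-to-volume for the reflectance
    axis (PC1), the covariate-only variant for the patterning axis (PC2),
    where smooth terms are also refit as cubic/quartic raw polynomials.
    """
    response = response.lower()
    if response not in ("pc1", "pc2"):
        raise ValueError("response must be 'pc1' or 'pc2'")
    missing = [
        c
        for c in REQUIRED_COVARIATES + (response,)
        if c not in table.columns
    ]
    if missing:
        raise KeyError(f"missing required columns: {missing}")
    data = table.reset_index(drop=True)

    # (i) does the site random intercept earn its keep? (REML, full fixed)
    full_terms: list[Term] = [("linear", "year"), ("linear", "latitude")]
    with_site = fit_model(data, response, full_terms, site=True,
                          criterion="REML", label="Year + latitude | site")
    without_site = fit_model(data, response, full_terms, site=False,
                             criterion="REML", label="Year + latitude")
    re_assessment = {
        "aicc_with_site": float(
            aicc(with_site.loglik, with_site.k, with_site.n)
        ),
        "aicc_without_site": float(
            aicc(without_site.loglik, without_site.k, without_site.n)
        ),
    }
    re_assessment["delta_aicc"] = (
        re_assessment["aicc_without_site"] - re_assessment["aicc_with_site"]
    )
    re_assessment["site_improves"] = bool(re_assessment["delta_aicc"] > 0)

    # (ii) spatio-temporal structure (ML)
    st_fits = [
        fit_model(data, response, terms, site=True, criterion="ML",
                  label=label)
        for label, terms in SPATIO_TEMPORAL_SET
    ]
    st = compare(st_fits, [label for label, _ in SPATIO_TEMPORAL_SET])

    # (iii) environmental structure (ML)
    env_set = (
        ENVIRONMENTAL_SET_FULL if response == "pc1"
        else ENVIRONMENTAL_SET_NULLISH
    )
    env_fits = [
        fit_model(data, response, terms, site=True, criterion="ML",
                  label=label)
        for label, terms in env_set
    ]
    env = compare(env_fits, [label for label, _ in env_set])

    return {
        "random_effect_assessment": re_assessment,
        "spatio_temporal": st,
        "environmental": env,
    }
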