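"""Study-level procedures: lesion classification, reliability filtering,
AIC model preference, method comparison, and group statistics.

Lesions are classified by expected myelin density from conventional MRI:
gadolinium enhancement marks active lesions; T1 intensity relative to NAWM
and CSF together with the T1-vs-FLAIR volume ratio separates black holes,
fully demyelinated, partially myelinated, and remyelinated lesions.  Only
lesions with at least one diameter above 3 mm are considered.
"""
from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


class T1Class(str, enum.Enum):
    ISO_TO_NAWM = "iso_to_NAWM"
    HYPOINTENSE = "hypointense"
    ISO_TO_CSF = "iso_to_CSF"


class LesionClass(str, enum.Enum):
    ACTIVE = "active"
    BLACK_HOLE = "black_hole"
    DEMYELINATED = "demyelinated"
    PARTIALLY_MYELINATED = "partially_myelinated"
    REMYELINATED = "remyelinated"
    EXCLUDED = "excluded"


#: the four myelin-density classes, ordered by increasing expected myelin
MYELIN_ORDER = (
    LesionClass.BLACK_HOLE,
    LesionClass.DEMYELINATED,
    LesionClass.PARTIALLY_MYELINATED,
    LesionClass.REMYELINATED,
)


@dataclasses.dataclass
class LesionDescriptor:
    lesion_id: str
    t2_flair_hyperintense: bool
    t1_class: T1Class
    post_gd_hyperintense: bool
    volume_t1_ml: float
    volume_t2flair_ml: float
    max_diameter_mm: float
    nawm_region: str = ""

    def __post_init__(self):
        self.t1_class = T1Class(self.t1_class)
        if self.volume_t1_ml <= 0 or self.volume_t2flair_ml <= 0:
            raise ValueError("lesion volumes must be positive")
        if self.max_diameter_mm <= 0:
            raise ValueError("max diameter must be positive")


def classify_lesion(d: LesionDescriptor, volume_equal_tol: float = 0.2) -> LesionClass:
    """Map an MRI lesion descriptor to its myelin-density class.

    Priority: size exclusion (no diameter > 3 mm), then gadolinium
    enhancement (active), then T1 intensity.  T1-hypointense lesions split on
    the T1-vs-FLAIR volume ratio: a T1 volume smaller than the FLAIR volume
    beyond ``volume_equal_tol`` means the hypointense core underfills the
    FLAIR extent (partially myelinated); volumes equal within tolerance mean
    full demyelination.  T1 iso-intensity to NAWM in a FLAIR-hyperintense
    lesion indicates restored myelin (remyelinated).  Total and deterministic
    over the descriptor space; inconsistent descriptors are flagged in the
    log and classified by their T1 class.
    """
    if d.max_diameter_mm <= 3.0:
        return LesionClass.EXCLUDED
    if d.post_gd_hyperintense:
        return LesionClass.ACTIVE
    if d.t1_class is T1Class.ISO_TO_CSF:
        if not d.t2_flair_hyperintense:
            log.warning("lesion %s: T1 iso-to-CSF without FLAIR hyperintensity", d.lesion_id)
        return LesionClass.BLACK_HOLE
    if d.t1_class is T1Class.HYPOINTENSE:
        if d.volume_t1_ml < (1.0 - volume_equal_tol) * d.volume_t2flair_ml:
            return LesionClass.PARTIALLY_MYELINATED
        return LesionClass.DEMYELINATED
    # T1 iso-intense to NAWM
    if not d.t2_flair_hyperintense:
        log.warning("lesion %s: T1 iso-to-NAWM without FLAIR hyperintensity", d.lesion_id)
    return LesionClass.REMYELINATED


def filter_reliable(estimates: pd.DataFrame, threshold: float = 25.0,
                    se_col: str = "se_percent") -> tuple[pd.DataFrame, float]:
    """Drop estimates whose %SE exceeds the reliability threshold (default 25%).

    Returns the kept rows and the removed fraction.  Rows with non-finite %SE
    count as unreliable.
    """
    se = estimates[se_col].to_numpy(dtype=float)
    keep = np.isfinite(se) & (se <= threshold)
    removed = 1.0 - keep.mean() if se.size else 0.0
    return estimates.loc[keep].copy(), float(removed)


@dataclasses.dataclass
class PreferenceTable:
    """Per-group AIC winner votes and percentages over scored regions."""

    counts: pd.DataFrame      # index: group, columns: model, values: votes
    percentages: pd.DataFrame

    def preferred(self, group) -> str:
        return self.counts.loc[group].idxmax()


def model_preference(aic_table: pd.DataFrame, group_col: str | None = None) -> PreferenceTable:
    """Tally the lowest-AIC model per region; ties split their vote equally.

    ``aic_table`` needs columns ``region``, ``model``, ``aic`` and optionally
    a grouping column (e.g. tissue class); regions with a missing AIC entry
    are skipped with a log message.
    """
    required = {"region", "model", "aic"}
    if not required.issubset(aic_table.columns):
        raise ValueError(f"aic_table must have columns {sorted(required)}")
    models = sorted(aic_table["model"].unique())
    rows: dict[str, dict[str, float]] = {}
    for (region), sub in aic_table.groupby("region"):
        if sub["aic"].isna().any() or sub["model"].nunique() < 2:
            log.warning("region %s skipped: missing AIC entries", region)
            continue
        group = str(sub[group_col].iloc[0]) if group_col else "all"
        votes = rows.setdefault(group, {m: 0.0 for m in models})
        best = sub["aic"].min()
        winners = sub.loc[np.isclose(sub["aic"], best, rtol=0, atol=1e-12), "model"]
        if len(winners) > 1:
            log.warning("AIC tie in region %s; splitting vote", region)
        for mname in winners:
            votes[mname] += 1.0 / len(winners)
    counts = pd.DataFrame(rows).T.reindex(columns=models).fillna(0.0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return PreferenceTable(counts, pct)


@dataclasses.dataclass
class ComparisonResult:
    r: float
    slope: float
    intercept: float
    n: int
    group: str = "all"


def compare_methods(reference, candidate, group: str = "all") -> ComparisonResult:
    """Pearson r plus OLS slope/intercept of the candidate on the reference."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(candidate, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    fit = sps.linregress(x, y)
    return ComparisonResult(float(fit.rvalue), float(fit.slope), float(fit.intercept), x.size, group)


def group_difference(gm_values, wm_values, alpha: float = 0.05) -> dict:
    """Two-sample comparison with normality and equal-variance gates.

    Kolmogorov-Smirnov (against a normal with the sample's moments) flags
    non-normality per group at p < alpha; Levene's test gates between the
    pooled-variance Student's t (df = n1+n2-2) and Welch's correction.
    """
    x = np.asarray(gm_values, dtype=float)
    y = np.asarray(wm_values, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 values per group")

    def ks_normal(v):
        sd = v.std(ddof=1)
        if sd == 0:
            return 0.0
        return float(sps.kstest(v, "norm", args=(v.mean(), sd)).pvalue)

    ks_x, ks_y = ks_normal(x), ks_normal(y)
    lev_p = float(sps.levene(x, y).pvalue) if x.std() + y.std() > 0 else 1.0
    equal_var = lev_p >= alpha
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2
    else:  # Welch-Satterthwaite
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return {
        "t": float(t),
        "df": float(df),
        "p": float(p),
        "test_used": "student_t" if equal_var else "welch_t",
        "normal_p": (ks_x, ks_y),
        "levene_p": lev_p,
    }


def lesion_vs_nawm(lesion_values, nawm_values) -> dict:
    """Two-sided Mann-Whitney U of lesion values against NAWM.

    Exact null distribution for min(n1, n2) <= 8 without ties, normal
    approximation with tie correction otherwise.  U is the count of
    (lesion, NAWM) pairs where the lesion value exceeds the NAWM value
    (plus half-ties).
    """
    x = np.asarray(lesion_values, dtype=float)
    y = np.asarray(nawm_values, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}
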