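"""Expression statistics: spot-change detection, PCA, QPCR fold changes,
and the two-round NMD-target validation.

The differential tests deliberately mirror a classical proteomics /
QPCR workflow: equal-variance Student t-tests on log abundances with raw
(uncorrected) p-value thresholds — a two-tailed p < 0.01 for gel spots
and a one-tailed p < 0.05 for QPCR fold changes. No multiple-testing
correction is applied anywhere; callers comparing many spots should
interpret the raw p-values accordingly.

A gene is a *bona fide* NMD target only when its mRNA increases
significantly in response to both the knockdown of the decay factor
(round 1) and translation inhibition by cycloheximide (round 2); the
second round is only run for genes that passed the first, mirroring a
staged study design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("increased", "no_change", "decreased", "no_signal")


@dataclass
class SpotMatrix:
    """Spots x samples log-abundance table with condition labels.

    ``values`` holds log abundances (base ``log_base``); missing spots are
    NaN. ``conditions`` maps each sample (column) to its condition label.
    """

    values: pd.DataFrame
    conditions: pd.Series
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions.index[self.conditions.isna()])
            raise ValueError(f"samples without a condition label: {missing}")

    def samples_for(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass(frozen=True)
class SpotChange:
    spot_id: str
    fold_change: float
    p_value: float
    direction: str  # "up" | "down"


@dataclass
class PCAResult:
    """Mean-centred PCA of samples over spot variables."""

    scores: np.ndarray       # samples x components
    loadings: np.ndarray     # spots x components
    explained: np.ndarray    # per-component variance fraction
    @property
    def r2_cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained)


@dataclass
class QPCRFold:
    gene: str
    condition: str
    folds: np.ndarray        # one normalized fold change per replicate
    @property
    def mean(self) -> float:
        return float(np.mean(self.folds))
    @property
    def sem(self) -> float:
        return float(stats.sem(self.folds))


@dataclass
class ValidationOutcome:
    gene: str
    round1: str              # increased | no_change | decreased | no_signal
    round2: str              # same, or not_tested
    @property
    def bona_fide_nmd(self) -> bool:
        return self.round1 == "increased" and self.round2 == "increased"


@dataclass
class SummaryTable:
    """Category counts with half-up rounded integer percentages."""

    counts: dict[str, int]
    denominator: int
    strict: bool = True
    percentages: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if self.strict and total != self.denominator:
            raise ValueError(
                f"counts sum to {total}, denominator is {self.denominator}"
            )
        # exact rational arithmetic: float division could misround x.5 cases
        self.percentages = {
            k: int(
                (Decimal(100 * v) / Decimal(self.denominator)).quantize(
                    Decimal(1), rounding=ROUND_HALF_UP
                )
            )
            for k, v in self.counts.items()
        }


def round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Spot-level statistics
# ---------------------------------------------------------------------------

def filter_presence(matrix: SpotMatrix, min_fraction: float = 0.75) -> SpotMatrix:
    """Drop spots observed in fewer than ``min_fraction`` of the samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    frac = matrix.values.notna().mean(axis=1)
    kept = matrix.values.loc[frac >= min_fraction]
    if kept.empty:
        raise ValueError("presence filter removed every spot")
    return SpotMatrix(values=kept, conditions=matrix.conditions, log_base=matrix.log_base)


def spot_ttest(
    matrix: SpotMatrix, treat: str, ctrl: str, equal_var: bool = True
) -> list[SpotChange]:
    """Per-spot two-sample Student t-test of treatment vs control.

    Performed on log abundances; ``fold_change`` is the linear-scale ratio
    ``log_base ** (mean_treat - mean_ctrl)``. Spots with fewer than two
    non-missing values in either group get p = NaN. Spots with zero
    variance in both groups get p = 1 when means are equal, p = 0
    otherwise. Ties in direction are reported as "up".
    """
    t_cols = matrix.samples_for(treat)
    c_cols = matrix.samples_for(ctrl)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 samples per compared condition")
    tv = matrix.values[t_cols].to_numpy(dtype=float)
    cv = matrix.values[c_cols].to_numpy(dtype=float)
    out: list[SpotChange] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for spot_id, trow, crow in zip(matrix.values.index, tv, cv):
            t_obs = trow[~np.isnan(trow)]
            c_obs = crow[~np.isnan(crow)]
            diff = float(np.mean(t_obs) - np.mean(c_obs)) if len(t_obs) and len(c_obs) else np.nan
            if len(t_obs) < 2 or len(c_obs) < 2:
                p = np.nan
            elif np.var(t_obs) == 0 and np.var(c_obs) == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                p = float(stats.ttest_ind(t_obs, c_obs, equal_var=equal_var).pvalue)
            fold = float(matrix.log_base ** diff) if not np.isnan(diff) else np.nan
            out.append(
                SpotChange(
                    spot_id=str(spot_id),
                    fold_change=fold,
                    p_value=p,
                    direction="down" if diff < 0 else "up",
                )
            )
    return out


def significant_spots(
    changes: Iterable[SpotChange], alpha: float = 0.01, direction: str | None = None
) -> set[str]:
    """Spot ids with p < alpha, optionally restricted to one direction."""
    return {
        c.spot_id
        for c in changes
        if not np.isnan(c.p_value)
        and c.p_value < alpha
        and (direction is None or c.direction == direction)
    }


def common_changes(set_a: set[str], set_b: set[str]) -> tuple[int, int, int]:
    """(unique to A, unique to B, common) counts of two spot-change sets."""
    set_a, set_b = set(set_a), set(set_b)
    common = set_a & set_b
    return (len(set_a - common), len(set_b - common), len(common))


def pca_fit(matrix: SpotMatrix, n_components: int = 8) -> PCAResult:
    """Mean-centred PCA of the samples (observations) over spots (variables).

    Remaining missing values (after the presence filter) are imputed with
    the spot-wise mean. Scores are reproducible up to per-component sign.
    """
    from sklearn.decomposition import PCA

    filled = matrix.values.apply(lambda row: row.fillna(row.mean()), axis=1)
    x = filled.to_numpy(dtype=float).T  # samples x spots
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# QPCR
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("gene", "sample", "condition", "quantity_goi", "quantity_reference")


def read_qpcr_tsv(text: str) -> pd.DataFrame:
    """Parse QPCR records; non-positive quantities are rejected."""
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"QPCR table lacks columns: {sorted(missing)}")
    if (df["quantity_goi"] <= 0).any() or (df["quantity_reference"] <= 0).any():
        raise ValueError("QPCR quantities must be > 0")
    return df


def qpcr_fold_change(
    records: pd.DataFrame, gene: str, condition: str, control: str = "control"
) -> QPCRFold:
    """Reference-normalized fold changes of a gene relative to control.

    Per replicate the gene-of-interest quantity is normalized to the
    reference gene (GAPDH/HPRT role); each treatment ratio is then divided
    by the mean control ratio.
    """
    sub = records[records["gene"] == gene]
    ratios = sub["quantity_goi"] / sub["quantity_reference"]
    ctrl_ratio = ratios[sub["condition"] == control]
    cond_ratio = ratios[sub["condition"] == condition]
    if ctrl_ratio.empty or cond_ratio.empty:
        raise ValueError(f"{gene}: need >= 1 replicate in both {condition!r} and {control!r}")
    folds = (cond_ratio / ctrl_ratio.mean()).to_numpy(dtype=float)
    return QPCRFold(gene=gene, condition=condition, folds=folds)


def _classify_round(folds: Sequence[float] | None, alpha: float) -> str:
    if folds is None:
        return "no_signal"
    arr = np.asarray(folds, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        return "no_signal"
    logs = np.log(arr)
    if np.all(logs == logs[0]):
        return "no_change" if logs[0] == 0 else ("increased" if logs[0] > 0 else "decreased")
    p_up = stats.ttest_1samp(logs, 0.0, alternative="greater").pvalue
    if p_up < alpha:
        return "increased"
    p_down = stats.ttest_1samp(logs, 0.0, alternative="less").pvalue
    if p_down < alpha:
        return "decreased"
    return "no_change"


def two_round_validate(
    gene: str,
    kd_folds: Sequence[float] | None,
    chx_folds: Sequence[float] | None,
    alpha: float = 0.05,
    always_test_round2: bool = False,
) -> ValidationOutcome:
    """Stage the knockdown (round 1) and cycloheximide (round 2) tests.

    Each round is a one-tailed one-sample Student t-test of the log fold
    changes against 0 at ``alpha``: significantly positive -> increased,
    significantly negative -> decreased, else no_change; fewer than two
    usable replicates -> no_signal. Round 2 is evaluated only for genes
    that increased in round 1 unless ``always_test_round2``.
    """
    round1 = _classify_round(kd_folds, alpha)
    if round1 == "increased" or always_test_round2:
        round2 = _classify_round(chx_folds, alpha)
    else:
        round2 = "not_tested"
    return ValidationOutcome(gene=gene, round1=round1, round2=round2)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_categories(
    counts: Mapping[str, int], denominator: int, strict: bool = True
) -> SummaryTable:
    """Integer-percentage summary table (half-up rounding).

    By default the counts must sum to the denominator. ``strict=False``
    permits a mismatch for reporting percentages against an externally
    fixed denominator (published tables are occasionally internally
    inconsistent in exactly this way).
    """
    return SummaryTable(counts=dict(counts), denominator=denominator, strict=strict)


def summarize_outcomes(outcomes: Iterable[ValidationOutcome], which: str = "round1") -> SummaryTable:
    """Tally validation outcomes for one round into a SummaryTable."""
    counts = {c: 0 for c in CATEGORIES}
    n = 0
    for o in outcomes:
        cat = getattr(o, which)
        if cat == "not_tested":
            continue
        counts[cat] += 1
        n += 1
    return summarize_categories(counts, n)


def percent_isoform(upper_intensity: float, lower_intensity: float) -> float:
    """Percent of total band signal in the upper (NMD-sensitive) band."""
    if upper_intensity < 0 or lower_intensity < 0:
        raise ValueError("band intensities must be >= 0")
    total = upper_intensity + lower_intensity
    if total == 0:
        raise ValueError("both band intensities are zero")
    return 100.0 * upper_intensity / total
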