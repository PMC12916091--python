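"""Neuropsychological battery -> four domain scores and a global score.

The battery holds 21 tests mapped to four domains (memory, executive,
language, visuospatial).  Processing order:

1. ``transform_tests`` — natural-log transform of the three
   skew-normalized tests (Hooper Visual Organization Test, Trail Making
   part A, Trail Making part B) and a sign flip for tests where lower raw
   scores mean better performance, so that afterwards higher = better for
   every test.
2. ``impute_chained`` — multiple imputation by chained equations:
   per-column linear regressions on all other tests, iterated, with a
   stochastic normal residual draw (predictive-mean matching available),
   producing ``m`` completed tables.  Observed cells are never altered.
3. ``zscore_tests`` — column standardization to mean 0, SD 1 (n-1).
4. ``domain_scores`` — domain = mean of member-test z-scores, global =
   mean of the four domains, averaged over the ``m`` completed tables.

The shipped 21-test list is a synthetic stand-in battery: the domain
membership counts and the three log-transform tests are fixed, but site
batteries can swap in their own mapping via a YAML spec file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .tap_features import standardize_columns

DOMAINS = ("memory", "executive", "language", "visuospatial")


@dataclass(frozen=True)
class TestSpec:
    """One neuropsychological test: its domain, and how to orient it."""

    name: str
    domain: str
    log_transform: bool = False
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"test '{self.name}': unknown domain '{self.domain}'")


# Synthetic default battery: 21 tests over 4 domains; the three
# log-transform tests are Hooper (higher better) and Trails A/B (timed,
# lower better).
_DEFAULT_SPEC_ROWS = (
    ("logical_memory_immediate", "memory", False, True),
    ("logical_memory_delayed", "memory", False, True),
    ("logical_memory_recognition", "memory", False, True),
    ("visual_reproduction_immediate", "memory", False, True),
    ("visual_reproduction_delayed", "memory", False, True),
    ("visual_reproduction_recognition", "memory", False, True),
    ("paired_associates_immediate", "memory", False, True),
    ("paired_associates_delayed", "memory", False, True),
    ("trail_making_a", "executive", True, False),
    ("trail_making_b", "executive", True, False),
    ("digit_span_forward", "executive", False, True),
    ("digit_span_backward", "executive", False, True),
    ("similarities", "executive", False, True),
    ("digit_symbol_coding", "executive", False, True),
    ("boston_naming", "language", False, True),
    ("category_fluency", "language", False, True),
    ("reading_recognition", "language", False, True),
    ("verbal_comprehension", "language", False, True),
    ("hooper_visual_organization", "visuospatial", True, True),
    ("block_design", "visuospatial", False, True),
    ("clock_drawing", "visuospatial", False, True),
)


def default_test_specs() -> list[TestSpec]:
    """The shipped 21-test battery specification."""
    return [TestSpec(*row) for row in _DEFAULT_SPEC_ROWS]


def load_test_specs(path) -> list[TestSpec]:
    """Read a test-spec YAML: a list of mappings with keys
    ``name, domain, log_transform, higher_is_better``."""
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    return [
        TestSpec(
            name=row["name"],
            domain=row["domain"],
            log_transform=bool(row.get("log_transform", False)),
            higher_is_better=bool(row.get("higher_is_better", True)),
        )
        for row in rows
    ]


def write_test_specs(specs: list[TestSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "name": s.name,
                    "domain": s.domain,
                    "log_transform": s.log_transform,
                    "higher_is_better": s.higher_is_better,
                }
                for s in specs
            ],
            fh,
            sort_keys=False,
        )


def test_columns(specs: list[TestSpec]) -> list[str]:
    return [s.name for s in specs]


def transform_tests(raw: pd.DataFrame, specs: list[TestSpec]) -> pd.DataFrame:
    """Log-transform and direction-adjust raw test scores.

    Log-transform tests must be strictly positive; a nonpositive value
    raises with the offending row identified.  The direction adjustment
    is a sign flip applied after any transform, so higher always means
    better downstream.  Non-test columns pass through unchanged.
    """
    out = raw.copy()
    for spec in specs:
        if spec.name not in out.columns:
            raise ValueError(f"test column '{spec.name}' missing from table")
        x = out[spec.name].astype(float)
        if spec.log_transform:
            bad = x[x.notna() & (x <= 0)]
            if len(bad):
                raise ValueError(
                    f"nonpositive value in log-transform test '{spec.name}' "
                    f"at row(s) {list(bad.index[:5])}"
                )
            x = np.log(x)
        if not spec.higher_is_better:
            x = -x
        out[spec.name] = x
    return out


def impute_chained(
    table: pd.DataFrame,
    m: int = 5,
    n_iter: int = 10,
    seed: int = 0,
    method: str = "norm",
    pmm_k: int = 5,
) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations on a numeric table.

    Missing cells start at their column mean; each of ``n_iter`` sweeps
    refits, column by column, a linear regression of the column on all
    other columns over the originally observed rows (predictors taken at
    their current completed values) and overwrites the missing cells with
    prediction plus noise — a normal residual draw (``method='norm'``) or
    a predictive-mean-matching donor value (``method='pmm'``, ``pmm_k``
    nearest donors).  ``m`` independent chains run from sub-seeds derived
    from ``seed``; observed cells are never altered.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if method not in ("norm", "pmm"):
        raise ValueError("method must be 'norm' or 'pmm'")
    X = table.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n, p = X.shape
    for j, col in enumerate(table.columns):
        if obs[:, j].sum() < 2:
            raise ValueError(f"column '{col}' has fewer than 2 observed values")
    if obs.all():
        return [table.copy() for _ in range(m)]

    col_means = np.nanmean(X, axis=0)
    completed = []
    missing_cols = [j for j in range(p) if not obs[:, j].all()]
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(chain))))
        Xc = X.copy()
        for j in range(p):
            Xc[~obs[:, j], j] = col_means[j]
        for _ in range(n_iter):
            for j in missing_cols:
                rows = obs[:, j]
                others = [k for k in range(p) if k != j]
                A = np.column_stack([np.ones(n), Xc[:, others]])
                Ao = A[rows]
                # normal equations (tiny ridge for numerical safety);
                # fall back to lstsq if singular
                AtA = Ao.T @ Ao
                AtA[np.diag_indices_from(AtA)] += 1e-10
                try:
                    beta = np.linalg.solve(AtA, Ao.T @ X[rows, j])
                except np.linalg.LinAlgError:
                    beta, *_ = np.linalg.lstsq(Ao, X[rows, j], rcond=None)
                fitted_obs = Ao @ beta
                resid = X[rows, j] - fitted_obs
                dof = rows.sum() - A.shape[1]
                sigma = np.sqrt((resid @ resid) / dof) if dof > 0 else resid.std()
                pred = A[~rows] @ beta
                if method == "norm":
                    fill = pred + rng.normal(0.0, sigma, pred.size)
                else:
                    donors_y = X[rows, j]
                    fill = np.empty(pred.size)
                    for i, pv in enumerate(pred):
                        near = np.argsort(np.abs(fitted_obs - pv))[: min(pmm_k, donors_y.size)]
                        fill[i] = donors_y[rng.choice(near)]
                Xc[~rows, j] = fill
        completed.append(pd.DataFrame(Xc, index=table.index, columns=table.columns))
    return completed


def zscore_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (mean 0, SD 1 with the n-1 denominator); shares the
    standardization contract of the tapping feature matrix."""
    return standardize_columns(table)


def domain_scores(
    z_tables: pd.DataFrame | list[pd.DataFrame], specs: list[TestSpec]
) -> pd.DataFrame:
    """Domain and global scores, averaged over ``m`` completed tables.

    Per table: each domain is the mean of its member tests' z-scores and
    the global score the mean of the four domains; the final score is the
    element-wise mean across the tables.
    """
    if isinstance(z_tables, pd.DataFrame):
        z_tables = [z_tables]
    by_domain: dict[str, list[str]] = {d: [] for d in DOMAINS}
    for spec in specs:
        by_domain[spec.domain].append(spec.name)
    acc = None
    for z in z_tables:
        extra = set(z.columns) - {s.name for s in specs}
        if extra:
            raise ValueError(f"tests with no domain mapping: {sorted(extra)}")
        missing = {s.name for s in specs} - set(z.columns)
        if missing:
            raise ValueError(f"test columns absent from table: {sorted(missing)}")
        scores = pd.DataFrame(index=z.index)
        for domain, members in by_domain.items():
            scores[domain] = z[members].mean(axis=1)
        scores["global"] = scores[list(DOMAINS)].mean(axis=1)
        acc = scores if acc is None else acc + scores
    result = acc / len(z_tables)
    result.index.name = z_tables[0].index.name
    return result


def score_battery(
    neuro: pd.DataFrame,
    specs: list[TestSpec] | None = None,
    m: int = 5,
    n_iter: int = 10,
    seed: int = 0,
    method: str = "norm",
) -> pd.DataFrame:
    """Full pipeline: transform -> impute (m tables) -> z-score -> domain
    and global scores, for a neuro table indexed by ``participant_id``."""
    if specs is None:
        specs = default_test_specs()
    cols = test_columns(specs)
    table = neuro.set_index("participant_id")[cols] if "participant_id" in neuro.columns else neuro[cols]
    transformed = transform_tests(table, specs)
    completed = impute_chained(transformed, m=m, n_iter=n_iter, seed=seed, method=method)
    z_tables = [zscore_tests(t) for t in completed]
    return domain_scores(z_tables, specs)
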