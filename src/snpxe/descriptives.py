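"""Companion summaries: allele/MAF info, SNP main effects, outcome grids.

These mirror the helper computations that accompany a pattern search:
per-SNP allele bookkeeping, a single-SNP association test under each
of the three inheritance modes, and genotype-by-environment tables of
outcome proportions with an optional heat-table rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .fitstats import fit_glm
from .patterns import Direction, InheritanceMode, code_snp

__all__ = [
    "SNPInfo",
    "MainEffectResult",
    "GridTable",
    "maf_info",
    "recode_minor_count",
    "snp_main",
    "grid_proportions",
    "render_heattable",
]

_MISSING_TOKENS = {"", "NA", ".", "NN", "nan"}


@dataclass
class SNPInfo:
    """Allele summary for one SNP column."""

    snp_name: str
    major_allele: str | None
    minor_allele: str | None
    maf: float
    missing_pct: float
    monomorphic: bool
    allele_coded: bool  # True when the source column held allele-pair strings


@dataclass
class MainEffectResult:
    """Single-SNP association under the three inheritance modes."""

    snp_name: str
    per_mode: pd.DataFrame  # columns: mode, coefficient, se, p, bic
    best_mode: InheritanceMode | None
    p_snpiv: float | None


@dataclass
class GridTable:
    """Outcome proportions and cell sizes by genotype x environment level."""

    proportions: pd.DataFrame  # genotype rows x env-level columns
    counts: pd.DataFrame
    overall_n: int
    snp_name: str = "SNP"
    env_name: str = "env"


def _is_missing_token(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    return isinstance(v, str) and v.strip() in _MISSING_TOKENS


def maf_info(genotype_col, snp_name: str = "SNP") -> SNPInfo:
    """Allele summary: major/minor alleles, MAF, missingness.

    Accepts either unordered allele-pair strings ("AG" == "GA") or
    numeric 0/1/2 minor-allele counts.  Allele frequencies count two
    alleles per non-missing subject; the minor allele is the less
    frequent one (tie: alphabetically later).  Numeric input yields
    ``maf = mean/2`` with the alleles unnamed.
    """
    s = pd.Series(genotype_col)
    if len(s) == 0:
        raise ValueError(f"{snp_name}: empty genotype column")
    n_total = len(s)
    if pd.api.types.is_numeric_dtype(s):
        vals = s.dropna()
        bad = vals[~vals.isin([0, 1, 2])]
        if len(bad):
            raise ValueError(
                f"{snp_name}: numeric genotypes must be 0/1/2; got {bad.unique()[:5]}"
            )
        missing_pct = 100.0 * (n_total - len(vals)) / n_total
        if len(vals) == 0:
            raise ValueError(f"{snp_name}: all genotypes missing")
        maf = float(vals.mean() / 2.0)
        return SNPInfo(snp_name, None, None, maf, missing_pct,
                       monomorphic=vals.nunique() == 1, allele_coded=False)
    counts: dict[str, int] = {}
    n_missing = 0
    for v in s:
        if _is_missing_token(v):
            n_missing += 1
            continue
        v = str(v).strip()
        if len(v) != 2:
            raise ValueError(f"{snp_name}: genotype {v!r} is not a 2-allele pair")
        for a in v:
            counts[a] = counts.get(a, 0) + 1
    if not counts:
        raise ValueError(f"{snp_name}: all genotypes missing")
    if len(counts) > 2:
        raise ValueError(
            f"{snp_name}: more than 2 alleles observed ({sorted(counts)}); "
            "multi-allelic SNPs are not supported"
        )
    missing_pct = 100.0 * n_missing / n_total
    if len(counts) == 1:
        (allele,) = counts
        return SNPInfo(snp_name, allele, allele, 0.0, missing_pct,
                       monomorphic=True, allele_coded=True)
    # tie at 0.5: minor = alphabetically later allele
    (a1, c1), (a2, c2) = sorted(counts.items())
    if c1 == c2:
        major, minor = a1, a2
    elif c1 > c2:
        major, minor = a1, a2
    else:
        major, minor = a2, a1
    maf = counts[minor] / (counts[major] + counts[minor])
    return SNPInfo(snp_name, major, minor, maf, missing_pct,
                   monomorphic=False, allele_coded=True)


def recode_minor_count(genotype_col, info: SNPInfo) -> pd.Series:
    """Convert allele-pair strings to 0/1/2 minor-allele counts."""
    if not info.allele_coded:
        return pd.Series(genotype_col, dtype=float)
    out = []
    for v in pd.Series(genotype_col):
        if _is_missing_token(v):
            out.append(np.nan)
            continue
        v = str(v).strip()
        extraneous = set(v) - {info.major_allele, info.minor_allele}
        if extraneous:
            raise ValueError(
                f"{info.snp_name}: allele(s) {sorted(extraneous)} not among "
                f"major={info.major_allele}/minor={info.minor_allele}"
            )
        out.append(0.0 if info.monomorphic else float(v.count(info.minor_allele)))
    return pd.Series(out, index=pd.Series(genotype_col).index)


def snp_main(
    data: pd.DataFrame,
    snp_name: str,
    outcome_name: str,
    family: str = "logistic",
    covariates: list[str] | None = None,
    criterion: str = "pvalue",
) -> MainEffectResult:
    """Test a single SNP's association under each inheritance mode.

    Fits outcome ~ coded SNP (+ covariates) once per mode; the per-mode
    p-value is the Wald p of the SNP coefficient.  The best mode has
    the smallest p-value (``criterion="bic"`` selects by BIC instead);
    ties go to additive.  A monomorphic SNP yields missing results.
    """
    covariates = covariates or []
    cols = [outcome_name, snp_name] + list(covariates)
    cc = data[cols].dropna().reset_index(drop=True)
    y = cc[outcome_name].to_numpy(dtype=float)
    g = cc[snp_name].to_numpy(dtype=float)
    rows = []
    mode_order = [InheritanceMode.ADDITIVE, InheritanceMode.DOMINANT, InheritanceMode.RECESSIVE]
    for mode in mode_order:
        coded = code_snp(g, mode, Direction.ORIGINAL)
        row = {"mode": mode.value, "coefficient": np.nan, "se": np.nan,
               "p": np.nan, "bic": np.nan}
        if np.nanstd(coded) > 0:
            design = pd.DataFrame({"const": 1.0, "SNP": coded})
            for c in covariates:
                design[c] = cc[c].to_numpy(dtype=float)
            fit = fit_glm(design, y, family)
            if fit.converged:
                est, se = fit.params["SNP"], fit.bse["SNP"]
                row.update(
                    coefficient=est, se=se,
                    p=2.0 * st.norm.sf(abs(est) / se) if se > 0 else np.nan,
                    bic=-2.0 * fit.log_likelihood + fit.n_params * np.log(fit.n_used),
                )
        rows.append(row)
    per_mode = pd.DataFrame(rows)
    key = "p" if criterion == "pvalue" else "bic"
    if criterion not in ("pvalue", "bic"):
        raise ValueError(f"criterion must be 'pvalue' or 'bic', got {criterion!r}")
    if per_mode[key].isna().all():
        return MainEffectResult(snp_name, per_mode, None, None)
    # idxmin returns the first (= additive-first) row on ties
    i = int(per_mode[key].idxmin())
    best_mode = mode_order[i]
    return MainEffectResult(snp_name, per_mode, best_mode, float(per_mode.loc[i, "p"]))


def grid_proportions(
    data: pd.DataFrame, snp_name: str, env_name: str, outcome_name: str
) -> GridTable:
    """Outcome proportion and cell size per (genotype, environment) cell.

    Defined for binary outcomes; rows are the three genotypes 0/1/2
    (kept even when empty, with n=0 and a missing proportion), columns
    the observed environment levels.
    """
    cc = data[[outcome_name, snp_name, env_name]].dropna().reset_index(drop=True)
    y = cc[outcome_name]
    if not y.isin([0, 1]).all():
        raise ValueError("grid proportions are defined for a binary 0/1 outcome")
    g = cc[snp_name]
    if not g.isin([0, 1, 2]).all():
        raise ValueError("SNP column must hold 0/1/2 minor-allele counts")
    levels = sorted(cc[env_name].unique())
    genotypes = [0, 1, 2]
    props = pd.DataFrame(index=genotypes, columns=levels, dtype=float)
    ns = pd.DataFrame(0, index=genotypes, columns=levels, dtype=int)
    grouped = cc.groupby([snp_name, env_name])[outcome_name]
    for (gv, ev), vals in grouped:
        props.loc[int(gv), ev] = vals.mean()
        ns.loc[int(gv), ev] = len(vals)
    props.index.name = snp_name
    ns.index.name = snp_name
    return GridTable(proportions=props, counts=ns, overall_n=len(cc),
                     snp_name=snp_name, env_name=env_name)


def format_grid(grid: GridTable) -> str:
    """Plain-text heat-table: one 'p% (n)' entry per cell."""
    lines = [f"{grid.snp_name} \\ {grid.env_name}\t" + "\t".join(str(c) for c in grid.counts.columns)]
    for gt in grid.counts.index:
        cells = []
        for lvl in grid.counts.columns:
            n = int(grid.counts.loc[gt, lvl])
            p = grid.proportions.loc[gt, lvl]
            cells.append(f"{100 * p:.1f}% ({n})" if n > 0 else "- (0)")
        lines.append(f"{gt}\t" + "\t".join(cells))
    return "\n".join(lines)


def render_heattable(grid: GridTable, highlight=None, path=None, ax=None) -> str:
    """Render the grid as a color-scaled heat-table; always return the text form.

    ``highlight`` (a PatternSpec) draws a frame around the reference
    sub-groups the pattern's interaction terms leave at OR = 1.  The
    figure is written to ``path`` when given; the color scale is
    linear in the proportion over observed cells.
    """
    text = format_grid(grid)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(1.2 * len(grid.counts.columns) + 2, 4))
    else:
        fig = ax.figure
    vals = np.ma.masked_invalid(grid.proportions.to_numpy(dtype=float))
    im = ax.imshow(vals, cmap="YlOrRd", aspect="auto")
    ax.set_xticks(range(len(grid.counts.columns)), [str(c) for c in grid.counts.columns])
    ax.set_yticks(range(3), [str(i) for i in grid.counts.index])
    ax.set_xlabel(grid.env_name)
    ax.set_ylabel(grid.snp_name)
    for i, gt in enumerate(grid.counts.index):
        for j, lvl in enumerate(grid.counts.columns):
            n = int(grid.counts.loc[gt, lvl])
            p = grid.proportions.loc[gt, lvl]
            label = f"{100 * p:.1f}%\n({n})" if n > 0 else ""
            ax.text(j, i, label, ha="center", va="center", fontsize=9)
    if highlight is not None:
        _frame_reference_cells(ax, grid, highlight)
    fig.colorbar(im, ax=ax, label="outcome proportion")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return text


def _frame_reference_cells(ax, grid: GridTable, spec) -> None:
    """Outline cells where the pattern's interaction terms are all zero."""
    from matplotlib.patches import Rectangle

    levels = list(grid.counts.columns)
    env_codes, _ = _env_dummy_values(levels, spec)
    for i, gt in enumerate(grid.counts.index):
        s = code_snp([gt], spec.mode, spec.snp_dir)[0]
        for j, lvl in enumerate(levels):
            if s * env_codes[lvl] == 0:  # no interaction contribution
                ax.add_patch(Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                       edgecolor="black", linewidth=2.5))


def _env_dummy_values(levels, spec):
    from .patterns import code_env

    dummies, ref = code_env(levels, spec.env_dir, "ordinal")
    # per level: 1 if any dummy active (level != reference)
    active = {lvl: float(lvl != ref) for lvl in levels}
    return active, ref
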