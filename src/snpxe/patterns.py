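"""Interaction-pattern family for SNP-environment testing.

A pattern combines three components: the regression *model structure*
(which main effects accompany the interaction terms), the SNP
*inheritance mode* (how the 0/1/2 minor-allele count is recoded), and
the *risk direction* of each factor (which pole of the coding is the
reference group).  For an ordinal environmental factor the family has
27 members; for a categorical factor the 9 patterns that reverse the
environment coding are dropped, leaving 18.

Pattern labels follow the ``<Structure>_<M>E_<sd><ed>`` grammar, e.g.
``Int_RE_ro`` = interaction-only model, recessive SNP coding, SNP
direction reversed, environment direction original.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InheritanceMode",
    "Direction",
    "ModelStructure",
    "PatternSpec",
    "CodedDesign",
    "enumerate_patterns",
    "pattern_label",
    "parse_label",
    "code_snp",
    "code_env",
    "build_design",
]


class InheritanceMode(enum.Enum):
    """How a 0/1/2 minor-allele count enters the model."""

    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @property
    def letter(self) -> str:
        return {"additive": "A", "dominant": "D", "recessive": "R"}[self.value]


class Direction(enum.Enum):
    """Risk direction: which coding pole is the reference group."""

    ORIGINAL = "original"
    REVERSE = "reverse"

    @property
    def letter(self) -> str:
        return "o" if self is Direction.ORIGINAL else "r"


class ModelStructure(enum.Enum):
    """Main-effect structure accompanying the interaction terms."""

    FULL = "Full"
    MINT_SNP = "Mint_SNP"
    MINT_ENV = "Mint_Env"
    INT = "Int"


_MODE_BY_LETTER = {m.letter: m for m in InheritanceMode}
_DIR_BY_LETTER = {d.letter: d for d in Direction}

# Direction pairs meaningful per structure (others are span-redundant:
# flipping a factor's direction while its main effect is in the model
# leaves the column space unchanged).
_ALLOWED_DIR_PAIRS: dict[ModelStructure, list[tuple[Direction, Direction]]] = {
    ModelStructure.FULL: [(Direction.ORIGINAL, Direction.ORIGINAL)],
    ModelStructure.MINT_SNP: [
        (Direction.ORIGINAL, Direction.ORIGINAL),
        (Direction.REVERSE, Direction.ORIGINAL),
    ],
    ModelStructure.MINT_ENV: [
        (Direction.ORIGINAL, Direction.ORIGINAL),
        (Direction.ORIGINAL, Direction.REVERSE),
    ],
    ModelStructure.INT: [
        (Direction.ORIGINAL, Direction.ORIGINAL),
        (Direction.ORIGINAL, Direction.REVERSE),
        (Direction.REVERSE, Direction.ORIGINAL),
        (Direction.REVERSE, Direction.REVERSE),
    ],
}


@dataclass(frozen=True)
class PatternSpec:
    """One interaction pattern: structure x inheritance mode x directions."""

    structure: ModelStructure
    mode: InheritanceMode
    snp_dir: Direction
    env_dir: Direction

    def __post_init__(self) -> None:
        allowed = _ALLOWED_DIR_PAIRS[self.structure]
        if (self.snp_dir, self.env_dir) not in allowed:
            raise ValueError(
                f"direction pair ({self.snp_dir.value}, {self.env_dir.value}) "
                f"is redundant for structure {self.structure.value}; "
                f"allowed: {[(s.letter + e.letter) for s, e in allowed]}"
            )

    @property
    def label(self) -> str:
        return pattern_label(self)

    def __str__(self) -> str:
        return self.label


def pattern_label(spec: PatternSpec) -> str:
    """Canonical label, e.g. ``Mint_Env_DE_or``."""
    return (
        f"{spec.structure.value}_{spec.mode.letter}E_"
        f"{spec.snp_dir.letter}{spec.env_dir.letter}"
    )


def parse_label(label: str) -> PatternSpec:
    """Inverse of :func:`pattern_label`; accepts only the 27 canonical labels."""
    by_label = {s.label: s for s in enumerate_patterns("ordinal")}
    try:
        return by_label[label]
    except KeyError:
        valid = ", ".join(sorted(by_label))
        raise ValueError(f"unknown pattern label {label!r}; valid labels: {valid}") from None


def enumerate_patterns(env_type: str = "ordinal") -> list[PatternSpec]:
    """Enumerate the pattern family in deterministic order.

    Parameters
    ----------
    env_type : {"ordinal", "categorical"}
        For a categorical environment the reference level is chosen by
        the user, so patterns that reverse the environment direction
        (labels ending ``_or`` / ``_rr``) are excluded: 18 = 27 - 9.

    Returns
    -------
    list of PatternSpec, ordered by structure (Full, Mint_SNP,
    Mint_Env, Int), then inheritance mode (additive, dominant,
    recessive), then direction pair (oo, or, ro, rr).
    """
    if env_type not in ("ordinal", "categorical"):
        raise ValueError(f"env_type must be 'ordinal' or 'categorical', got {env_type!r}")
    specs = []
    for structure, mode in itertools.product(ModelStructure, InheritanceMode):
        for snp_dir, env_dir in _ALLOWED_DIR_PAIRS[structure]:
            if env_type == "categorical" and env_dir is Direction.REVERSE:
                continue
            specs.append(PatternSpec(structure, mode, snp_dir, env_dir))
    return specs


# -- genotype / environment coding -----------------------------------------

_SNP_CODING: dict[tuple[InheritanceMode, Direction], dict[int, float]] = {
    (InheritanceMode.ADDITIVE, Direction.ORIGINAL): {0: 0, 1: 1, 2: 2},
    (InheritanceMode.ADDITIVE, Direction.REVERSE): {0: 2, 1: 1, 2: 0},
    (InheritanceMode.DOMINANT, Direction.ORIGINAL): {0: 0, 1: 1, 2: 1},
    (InheritanceMode.DOMINANT, Direction.REVERSE): {0: 1, 1: 0, 2: 0},
    (InheritanceMode.RECESSIVE, Direction.ORIGINAL): {0: 0, 1: 0, 2: 1},
    (InheritanceMode.RECESSIVE, Direction.REVERSE): {0: 1, 1: 1, 2: 0},
}


def code_snp(genotypes, mode: InheritanceMode, direction: Direction = Direction.ORIGINAL):
    """Recode 0/1/2 minor-allele counts under an inheritance mode and direction.

    Missing values (NaN) stay missing.  Values outside {0, 1, 2, NaN}
    raise with the offending positions named.
    """
    g = np.asarray(genotypes, dtype=float)
    ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = np.flatnonzero(~ok)[:10]
        raise ValueError(
            f"genotype values must be 0/1/2 or missing; offending rows: {bad.tolist()}"
        )
    table = _SNP_CODING[(mode, direction)]
    out = np.full_like(g, np.nan)
    for raw, coded in table.items():
        out[g == raw] = coded
    return out


def code_env(
    env,
    direction: Direction = Direction.ORIGINAL,
    env_type: str = "ordinal",
    reference=None,
) -> tuple[pd.DataFrame, object]:
    """Dummy-code an environmental factor.

    Ordinal/original: reference = lowest observed level; ordinal/reverse:
    reference = highest.  Categorical: reference is user-supplied
    (default first level in sorted order) and the reverse direction is
    rejected.  Returns (indicator matrix with one column per
    non-reference level ordered by level, reference level).
    """
    s = pd.Series(env)
    levels = sorted(s.dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"environment has a single observed level ({levels}); need >= 2")
    if env_type == "categorical":
        if direction is Direction.REVERSE:
            raise ValueError("reverse direction is undefined for a categorical environment")
        ref = reference if reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed (levels: {levels})")
    elif env_type == "ordinal":
        ref = levels[-1] if direction is Direction.REVERSE else levels[0]
    else:
        raise ValueError(f"env_type must be 'ordinal' or 'categorical', got {env_type!r}")
    cols = {
        f"ENV_{lvl}vs{ref}": (s == lvl).astype(float).to_numpy()
        for lvl in levels
        if lvl != ref
    }
    dummies = pd.DataFrame(cols)
    dummies[s.isna().to_numpy()] = np.nan
    return dummies, ref


@dataclass
class CodedDesign:
    """Coded columns for one pattern, before assembly into a matrix."""

    snp_col: np.ndarray
    env_dummies: pd.DataFrame
    interaction_cols: pd.DataFrame
    structure: ModelStructure
    reference_env_level: object = None
    snp_main_included: bool = field(init=False)
    env_main_included: bool = field(init=False)

    def __post_init__(self) -> None:
        self.snp_main_included = self.structure in (
            ModelStructure.FULL,
            ModelStructure.MINT_SNP,
        )
        self.env_main_included = self.structure in (
            ModelStructure.FULL,
            ModelStructure.MINT_ENV,
        )


def build_design(
    snp_coded,
    env_dummies: pd.DataFrame,
    structure: ModelStructure,
    covariates: pd.DataFrame | None = None,
    reference_env_level=None,
) -> tuple[pd.DataFrame, CodedDesign]:
    """Assemble the full design matrix (with intercept) for a structure.

    Columns: ``const``; SNP main effect (Full, Mint_SNP); environment
    dummies (Full, Mint_Env); one interaction column per dummy
    (always); covariates (always, when given).
    """
    snp = np.asarray(snp_coded, dtype=float)
    n = len(snp)
    if len(env_dummies) != n or (covariates is not None and len(covariates) != n):
        raise ValueError("snp, environment and covariate inputs must have equal length")
    inter = env_dummies.mul(snp, axis=0)
    inter.columns = [f"SNP:{c}" for c in env_dummies.columns]
    coded = CodedDesign(
        snp_col=snp,
        env_dummies=env_dummies,
        interaction_cols=inter,
        structure=structure,
        reference_env_level=reference_env_level,
    )
    parts = [pd.Series(np.ones(n), name="const")]
    if coded.snp_main_included:
        parts.append(pd.Series(snp, name="SNP"))
    if coded.env_main_included:
        parts.append(env_dummies)
    parts.append(inter)
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True))
    design = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    return design, coded
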