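"""Classify per-(individual, species) relatedness timelines into recovery patterns.

After antibiotics, the strain occupying a species niche can persist, be
transiently displaced, or be replaced outright. Given the matrix of pairwise
relatedness calls across an individual's timepoints, each timeline is
assigned one of six mutually exclusive categories (the color codes follow
the field's summary-figure convention):

* PERSISTENT (green) — the pre-treatment strain is related to every later
  timepoint.
* TRANSIENT_RETURN (green*) — pre and last timepoints carry the same strain,
  but at least one intermediate timepoint carried an unrelated strain that
  was eventually displaced by the pre-strain.
* NEW_FROM_TREATMENT_END (red) — the pre-strain never returns, and the strain
  present at the end of treatment is related to every later timepoint.
* NEW_LATE (blue) — the pre-strain never returns; the replacement appears at
  the late intermediate timepoint and persists to the last sample. Layouts
  without a late timepoint can structurally never emit this category.
* NEW_PERMANENT (purple) — no relationship between the pre-strain and any
  post-treatment strain.
* INDETERMINATE (gray) — a strict majority of the pairwise comparisons could
  not be evaluated (low/absent coverage), or no other rule applies.

The rules are evaluated in the precedence order gray, green, green*, red,
blue, purple; anything left over falls to gray with a logged reason, so the
classifier is a total function of the call matrix.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .wss_core import PairwiseWss, RelatednessCall


class TimepointRole(str, enum.Enum):
    PRE = "PRE"
    END_OF_TREATMENT = "END_OF_TREATMENT"
    LATE = "LATE"
    INTERMEDIATE = "INTERMEDIATE"
    LAST = "LAST"


@dataclass(frozen=True)
class TimelineLayout:
    """Ordered timepoint labels with their roles in the treatment course."""

    labels: tuple[str, ...]
    roles: tuple[TimepointRole, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.roles):
            raise ConfigError("labels and roles must have equal length")
        if len(self.labels) < 2:
            raise ConfigError("a timeline needs at least two timepoints")
        for role in (TimepointRole.PRE, TimepointRole.LAST):
            if self.roles.count(role) != 1:
                raise ConfigError(f"exactly one {role.value} timepoint required")
        if self.roles[0] is not TimepointRole.PRE:
            raise ConfigError("PRE must precede all other timepoints")
        if self.roles[-1] is not TimepointRole.LAST:
            raise ConfigError("LAST must be the final timepoint")
        for role in (TimepointRole.END_OF_TREATMENT, TimepointRole.LATE):
            if self.roles.count(role) > 1:
                raise ConfigError(f"at most one {role.value} timepoint allowed")

    def __len__(self) -> int:
        return len(self.labels)

    def _index_of(self, role: TimepointRole) -> int | None:
        return self.roles.index(role) if role in self.roles else None

    @property
    def pre_index(self) -> int:
        return 0

    @property
    def last_index(self) -> int:
        return len(self.labels) - 1

    @property
    def end_of_treatment_index(self) -> int | None:
        return self._index_of(TimepointRole.END_OF_TREATMENT)

    @property
    def late_index(self) -> int | None:
        return self._index_of(TimepointRole.LATE)

    @property
    def intermediate_indices(self) -> tuple[int, ...]:
        """All timepoints that are neither PRE nor LAST."""
        return tuple(range(1, len(self.labels) - 1))


#: Three-timepoint course: pre-treatment, end of a single antibiotic, ~3 months out.
THREE_POINT_LAYOUT = TimelineLayout(
    ("Day0", "Day7", "Day90"),
    (TimepointRole.PRE, TimepointRole.END_OF_TREATMENT, TimepointRole.LAST),
)

#: Four-timepoint course after an antibiotic cocktail: pre, end of treatment,
#: a late intermediate, and ~6 months out.
FOUR_POINT_LAYOUT = TimelineLayout(
    ("Day0", "Day8", "Day42", "Day180"),
    (
        TimepointRole.PRE,
        TimepointRole.END_OF_TREATMENT,
        TimepointRole.LATE,
        TimepointRole.LAST,
    ),
)


class RecoveryCategory(str, enum.Enum):
    PERSISTENT = "PERSISTENT"
    TRANSIENT_RETURN = "TRANSIENT_RETURN"
    NEW_FROM_TREATMENT_END = "NEW_FROM_TREATMENT_END"
    NEW_LATE = "NEW_LATE"
    NEW_PERMANENT = "NEW_PERMANENT"
    INDETERMINATE = "INDETERMINATE"

    @property
    def color(self) -> str:
        return {
            "PERSISTENT": "green",
            "TRANSIENT_RETURN": "green*",
            "NEW_FROM_TREATMENT_END": "red",
            "NEW_LATE": "blue",
            "NEW_PERMANENT": "purple",
            "INDETERMINATE": "gray",
        }[self.value]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Reporting groups: the two "new strain at an intermediate timepoint"
#: colors (red, blue) are merged into a single group in cohort summaries.
MERGED_GROUPS = {
    RecoveryCategory.PERSISTENT: "persistent",
    RecoveryCategory.TRANSIENT_RETURN: "transient_return",
    RecoveryCategory.NEW_FROM_TREATMENT_END: "new_intermediate",
    RecoveryCategory.NEW_LATE: "new_intermediate",
    RecoveryCategory.NEW_PERMANENT: "new_permanent",
    RecoveryCategory.INDETERMINATE: "indeterminate",
}

GROUP_ORDER = ["persistent", "transient_return", "new_intermediate", "new_permanent", "indeterminate"]


@dataclass(frozen=True)
class RelatednessMatrix:
    """Symmetric matrix of relatedness calls over one timeline."""

    individual_id: str
    species_id: str
    calls: np.ndarray  # (T, T) object array of RelatednessCall
    layout: TimelineLayout

    def __post_init__(self):
        t = len(self.layout)
        if self.calls.shape != (t, t):
            raise ConfigError(
                f"call matrix shape {self.calls.shape} does not match layout ({t} timepoints)"
            )
        for i, j in itertools.combinations(range(t), 2):
            if self.calls[i, j] != self.calls[j, i]:
                raise ConfigError("relatedness matrix must be symmetric")

    @classmethod
    def from_pairwise(
        cls,
        pairwise: PairwiseWss,
        layout: TimelineLayout,
        individual_id: str,
        species_id: str,
    ) -> "RelatednessMatrix":
        return cls(individual_id, species_id, pairwise.calls(), layout)


@dataclass(frozen=True)
class Classification:
    category: RecoveryCategory
    reason: str


def classify_timeline(
    matrix: RelatednessMatrix | np.ndarray, layout: TimelineLayout | None = None
) -> Classification:
    """Map one timeline's call matrix to its recovery category.

    Accepts either a :class:`RelatednessMatrix` or a bare (T, T) call array
    plus a layout. Total over all possible call matrices; precedence gray →
    green → green* → red → blue → purple, residue to gray.
    """
    if isinstance(matrix, RelatednessMatrix):
        calls, layout = matrix.calls, matrix.layout
    else:
        if layout is None:
            raise ConfigError("a layout is required with a bare call matrix")
        calls = matrix
        if calls.shape != (len(layout), len(layout)):
            raise ConfigError("call matrix shape does not match layout")

    t = len(layout)
    pre, last = layout.pre_index, layout.last_index
    pairs = list(itertools.combinations(range(t), 2))

    # equality, not identity: object arrays may hold the enums' str values
    n_indet = sum(1 for i, j in pairs if calls[i, j] == RelatednessCall.INDETERMINATE)
    if n_indet * 2 > len(pairs):
        return Classification(
            RecoveryCategory.INDETERMINATE,
            f"{n_indet}/{len(pairs)} pairs indeterminate (strict majority)",
        )

    rel = lambda i, j: calls[i, j] == RelatednessCall.RELATED
    unrel = lambda i, j: calls[i, j] == RelatednessCall.UNRELATED
    others = [i for i in range(t) if i != pre]

    if all(rel(pre, i) for i in others):
        return Classification(RecoveryCategory.PERSISTENT, "pre-strain related at every timepoint")

    if rel(pre, last) and any(unrel(pre, i) for i in layout.intermediate_indices):
        return Classification(
            RecoveryCategory.TRANSIENT_RETURN,
            "pre-strain back at last timepoint after an unrelated intermediate",
        )

    eot = layout.end_of_treatment_index
    if (
        unrel(pre, last)
        and eot is not None
        and all(rel(eot, i) for i in range(eot + 1, t))
    ):
        return Classification(
            RecoveryCategory.NEW_FROM_TREATMENT_END,
            "end-of-treatment strain persists to every later timepoint",
        )

    late = layout.late_index
    if unrel(pre, last) and late is not None and rel(late, last):
        return Classification(
            RecoveryCategory.NEW_LATE, "late-intermediate strain persists to last timepoint"
        )

    if all(unrel(pre, i) for i in others):
        return Classification(
            RecoveryCategory.NEW_PERMANENT, "pre-strain unrelated to every later timepoint"
        )

    return Classification(
        RecoveryCategory.INDETERMINATE, "no recovery rule applies (residual pattern)"
    )


def cohort_category_fractions(
    classifications: pd.DataFrame, merge_red_blue: bool = True
) -> pd.DataFrame:
    """Per-individual fraction of species falling into each category group.

    Expects columns ``individual_id``, ``species_id``, ``category``. With
    ``merge_red_blue`` the two intermediate-new-strain colors are reported as
    one group. Fractions sum to 1 over groups for every individual.
    """
    if classifications.empty:
        return pd.DataFrame(columns=["individual_id", *GROUP_ORDER])
    df = classifications.copy()
    cats = df["category"].map(
        lambda c: c if isinstance(c, RecoveryCategory) else RecoveryCategory(str(c))
    )
    if merge_red_blue:
        df["group"] = cats.map(MERGED_GROUPS)
        groups = GROUP_ORDER
    else:
        df["group"] = cats.map(lambda c: c.value.lower())
        groups = [c.value.lower() for c in RecoveryCategory]
    counts = df.groupby(["individual_id", "group"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=groups, fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    return frac.reset_index()


def select_top_species(pre_last_results: pd.DataFrame, k: int = 10) -> list[str]:
    """Rank species by how often their pre-vs-last comparison yields a score.

    ``pre_last_results`` holds one row per (individual, species) pre↔last
    comparison with columns ``species_id``, ``individual_id``, ``call`` and
    ``coverage`` (the pair's minimum genome-coverage fraction). Species are
    ranked by the number of individuals with a defined (non-INDETERMINATE)
    score, ties broken by mean coverage, then species id; the top ``k`` are
    returned. Fewer than ``k`` species triggers a warning and returns all.
    """
    df = pre_last_results.copy()
    df["defined"] = df["call"].map(
        lambda c: (c if isinstance(c, RelatednessCall) else RelatednessCall(str(c)))
        is not RelatednessCall.INDETERMINATE
    )
    ranking = (
        df.groupby("species_id")
        .agg(n_defined=("defined", "sum"), mean_coverage=("coverage", "mean"))
        .reset_index()
        .sort_values(
            ["n_defined", "mean_coverage", "species_id"], ascending=[False, False, True]
        )
    )
    species = ranking["species_id"].tolist()
    if len(species) < k:
        warnings.warn(
            f"only {len(species)} species observed; requested top {k}", stacklevel=2
        )
        return species
    return species[:k]
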