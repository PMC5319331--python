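"""Life-cycle state spaces for the two matrix designs.

Two designs are supported, mirroring the demography of the study systems:

* a *historical* (paired-stage) design, in which each matrix state is an
  ordered pair of life-history stages in consecutive years, so transition
  probabilities can depend on the previous year's state (used for the
  *Cypripedium* populations, order 395); and
* an *age x stage* design crossing discrete adult age classes with mature
  stages, with stasis in the final age class (used for *Ophrys sphegodes*,
  order 173).

Both spaces also carry the unmonitored juvenile pathway (seed, protocorm
and seedling stages), whose transition probabilities come from literature
configuration rather than fitted models.

Indexing is 0-based internally; exports use stage names.  Matrices built
on these spaces are column-to-row oriented: the column is the source
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

# stage classes
SEED = "seed"
PROTOCORM = "protocorm"
NEW_SEEDLING = "new_seedling"
SEEDLING = "seedling"
ADULT = "adult"


@dataclass(frozen=True)
class Stage:
    """One life-history stage.

    ``size`` is the sprout (or leaf) count; mature stages with size 0 are
    vegetatively dormant.  ``flowering`` implies ``size >= 1``.
    """

    name: str
    cls: str
    size: int = 0
    flowering: bool = False

    def __post_init__(self) -> None:
        if self.flowering and self.size < 1:
            raise InvalidArgumentError("a flowering stage needs size >= 1")

    @property
    def mature(self) -> bool:
        return self.cls == ADULT

    @property
    def dormant(self) -> bool:
        return self.mature and self.size == 0


def mature_stages(max_size: int) -> list[Stage]:
    """Dormant + vegetative sizes 1..max + flowering sizes 1..max."""
    if max_size < 1:
        raise InvalidArgumentError("max_size must be >= 1")
    out = [Stage("D", ADULT, 0, False)]
    out += [Stage(f"V{k}", ADULT, k, False) for k in range(1, max_size + 1)]
    out += [Stage(f"F{k}", ADULT, k, True) for k in range(1, max_size + 1)]
    return out


@dataclass(frozen=True)
class JuvenileColumn:
    """Structural recipe for one juvenile-pathway source column.

    The column's survival probability is looked up in the model's juvenile
    parameter map under ``surv_key``.  If ``sprout_key`` is set, the column
    has an emergence decision: with the looked-up probability the
    individual moves to one of ``targets`` (conditional ``weights``),
    otherwise to ``dormant_target``.  Fixed-path columns have
    ``sprout_key=None`` and move to ``targets`` with the given weights.
    """

    index: int
    surv_key: str
    targets: tuple[int, ...]
    #: conditional weights; floats are literal, strings are keys into the
    #: juvenile parameter map (resolved at matrix-build time)
    weights: tuple
    sprout_key: str | None = None
    dormant_target: int | None = None


@dataclass
class StateSpace:
    """Enumerated life-cycle states plus structural metadata.

    For ``kind == "historical"`` each state is a pair
    ``(stage in year t-1, stage in year t)``; for ``kind == "agestage"``
    each adult state is ``(age class, stage)`` and juveniles are single
    stages with ``age = 0``.
    """

    kind: str
    labels: list[str]
    curr_stage: list[Stage]
    prev_stage: list[Stage | None]       # historical only (None elsewhere)
    age: list[int]                       # agestage only (0 elsewhere)
    max_size: int
    max_age: int
    mature: list[Stage]
    juvenile_columns: list[JuvenileColumn]
    fecundity_target: int
    founder_index: int
    entry_stages: list[Stage]
    _adult_pair_index: dict = field(default_factory=dict, repr=False)

    # -- basic protocol ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def is_adult_column(self) -> np.ndarray:
        """True where the current stage is mature (adult vital rates apply)."""
        return np.array([s.mature for s in self.curr_stage])

    @property
    def is_flowering(self) -> np.ndarray:
        return np.array([s.flowering for s in self.curr_stage])

    @property
    def density_weights(self) -> np.ndarray:
        """Weight of each state in the population-density measure.

        Density feedback and plateau calibration count established plants
        (states whose current stage is mature), matching the field density
        estimate of adult individuals per square metre.
        """
        return self.is_adult_column.astype(float)

    # -- adult target lookup ----------------------------------------------
    def adult_pair_index(self, prev_name: str, curr_name: str) -> int:
        return self._adult_pair_index[(prev_name, curr_name)]

    def adult_targets(self, col: int) -> tuple[int, np.ndarray, np.ndarray]:
        """(dormancy target, vegetative target indices, flowering target
        indices by size 1..max) for an adult-rate source column."""
        j = self.curr_stage[col]
        if not j.mature:
            raise InvalidArgumentError("not an adult-rate column")
        m = self.max_size
        if self.kind == "historical":
            d = self._adult_pair_index[(j.name, "D")]
            tv = np.array([self._adult_pair_index[(j.name, f"V{k}")] for k in range(1, m + 1)])
            tf = np.array([self._adult_pair_index[(j.name, f"F{k}")] for k in range(1, m + 1)])
        else:
            a_next = min(self.age[col] + 1, self.max_age)
            d = self._adult_pair_index[(a_next, "D")]
            tv = np.array([self._adult_pair_index[(a_next, f"V{k}")] for k in range(1, m + 1)])
            tf = np.array([self._adult_pair_index[(a_next, f"F{k}")] for k in range(1, m + 1)])
        return d, tv, tf

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.labels):
            cur = self.curr_stage[i]
            prev = self.prev_stage[i]
            rows.append(
                {
                    "index": i,
                    "label": lab,
                    "class": cur.cls,
                    "size": cur.size,
                    "flowering": int(cur.flowering),
                    "age": self.age[i],
                    "prev_stage": prev.name if prev is not None else "",
                    "curr_stage": cur.name,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _historical_space(
    max_size: int,
    juvenile_plan: str,
    entry_names: tuple[str, ...],
) -> StateSpace:
    mats = mature_stages(max_size)
    by_name = {s.name: s for s in mats}
    entries = [by_name[n] for n in entry_names]

    labels: list[str] = []
    curr: list[Stage] = []
    prev: list[Stage | None] = []

    def add(p: Stage, c: Stage) -> int:
        labels.append(f"{p.name}|{c.name}")
        prev.append(p)
        curr.append(c)
        return len(labels) - 1

    juv: dict[str, Stage] = {}

    def jstage(name: str, cls: str, size: int = 0) -> Stage:
        juv.setdefault(name, Stage(name, cls, size, False))
        return juv[name]

    jcols: list[JuvenileColumn] = []

    if juvenile_plan == "cypripedium":
        seed = jstage("seed", SEED)
        p1 = jstage("P1", PROTOCORM)
        p2 = jstage("P2", PROTOCORM)
        p3 = jstage("P3", PROTOCORM)
        ns = jstage("NS", NEW_SEEDLING)
        s1 = [jstage(f"S1.{j}", SEEDLING, j) for j in range(3)]
        s2 = [jstage(f"S2.{j}", SEEDLING, j) for j in range(3)]

        i_seed_p1 = add(seed, p1)
        i_p1_p2 = add(p1, p2)
        i_p2_p3 = add(p2, p3)
        i_p3_ns = add(p3, ns)
        i_ns_s1 = [add(ns, s) for s in s1]
        i_s1_s2 = [[add(a, b) for b in s2] for a in s1]
        i_s2_e = [[add(a, e) for e in entries] for a in s2]

        # fixed protocorm path
        jcols.append(JuvenileColumn(i_seed_p1, "p1", (i_p1_p2,), (1.0,)))
        jcols.append(JuvenileColumn(i_p1_p2, "p2", (i_p2_p3,), (1.0,)))
        jcols.append(
            JuvenileColumn(i_p2_p3, "protocorm_to_seedling", (i_p3_ns,), (1.0,))
        )
        # new seedling decides whether to emerge with 1 or 2 sprouts
        jcols.append(
            JuvenileColumn(
                i_p3_ns, "ns",
                targets=(i_ns_s1[1], i_ns_s1[2]),
                weights=("one_sprout", "two_sprout"),
                sprout_key="seedling_sprout",
                dormant_target=i_ns_s1[0],
            )
        )
        for j in range(3):
            jcols.append(
                JuvenileColumn(
                    i_ns_s1[j], "s1",
                    targets=(i_s1_s2[j][1], i_s1_s2[j][2]),
                    weights=("one_sprout", "two_sprout"),
                    sprout_key="seedling_sprout",
                    dormant_target=i_s1_s2[j][0],
                )
            )
        nondorm_entries = [k for k, e in enumerate(entries) if not e.dormant]
        dorm_entry = next(k for k, e in enumerate(entries) if e.dormant)
        # (S1.j, S2.k) columns: the S2 plant decides its adult entry stage
        for j in range(3):
            for k in range(3):
                jcols.append(
                    JuvenileColumn(
                        i_s1_s2[j][k], "s2",
                        targets=tuple(i_s2_e[k][e] for e in nondorm_entries),
                        weights=tuple(f"entry_{entries[e].name}" for e in nondorm_entries),
                        sprout_key="entry_sprout",
                        dormant_target=i_s2_e[k][dorm_entry],
                    )
                )
        founder_entry = entries[nondorm_entries[0]]
        fec_target = i_seed_p1
        s2_names = {s.name for s in s2}
    elif juvenile_plan == "toy":
        seed = jstage("seed", SEED)
        p1 = jstage("P1", PROTOCORM)
        sdl = jstage("SDL", SEEDLING, 1)
        i_seed_p1 = add(seed, p1)
        i_p1_sdl = add(p1, sdl)
        i_sdl_e = [add(sdl, e) for e in entries]
        jcols.append(
            JuvenileColumn(i_seed_p1, "protocorm_to_seedling", (i_p1_sdl,), (1.0,))
        )
        nondorm_entries = [k for k, e in enumerate(entries) if not e.dormant]
        dorm_entry = next(k for k, e in enumerate(entries) if e.dormant)
        jcols.append(
            JuvenileColumn(
                i_p1_sdl, "sdl",
                targets=tuple(i_sdl_e[e] for e in nondorm_entries),
                weights=tuple(f"entry_{entries[e].name}" for e in nondorm_entries),
                sprout_key="entry_sprout",
                dormant_target=i_sdl_e[dorm_entry],
            )
        )
        founder_entry = entries[nondorm_entries[0]]
        fec_target = i_seed_p1
        s2_names = {sdl.name}
    else:
        raise InvalidArgumentError(f"unknown juvenile plan {juvenile_plan!r}")

    # adult block: all ordered pairs of mature stages
    pair_index: dict = {}
    for i_stage in mats:
        for j_stage in mats:
            idx = add(i_stage, j_stage)
            pair_index[(i_stage.name, j_stage.name)] = idx

    space = StateSpace(
        kind="historical",
        labels=labels,
        curr_stage=curr,
        prev_stage=prev,
        age=[0] * len(labels),
        max_size=max_size,
        max_age=0,
        mature=mats,
        juvenile_columns=jcols,
        fecundity_target=fec_target,
        founder_index=pair_index[(founder_entry.name, founder_entry.name)],
        entry_stages=entries,
    )
    space._adult_pair_index = pair_index
    space._final_seedling_names = s2_names  # type: ignore[attr-defined]
    return space


def cypripedium_state_space() -> StateSpace:
    """Historical stage-pair space for the *Cypripedium* design.

    19 mature stages (dormant + 1..9 sprouts vegetative + 1..9 sprouts
    flowering) paired across consecutive years give 361 adult states; the
    juvenile pathway (seed -> three protocorm stages -> new seedling ->
    1- and 2-year seedlings with 0..2 sprouts -> six adult entry stages)
    contributes 34 pair states, for 395 in total.

    The six adult entry stages (dormant, 1-2 sprouts vegetative, 1-2
    sprouts flowering, 3 sprouts vegetative) are a documented assumption:
    the entry-stage identity is overridable via :func:`historical_space`.
    """
    return _historical_space(
        max_size=9,
        juvenile_plan="cypripedium",
        entry_names=("D", "V1", "V2", "F1", "F2", "V3"),
    )


def toy_historical_space(
    max_size: int = 4,
    entry_names: tuple[str, ...] = ("D", "V1", "V2"),
) -> StateSpace:
    """Small historical space for tests and desk-scale fixtures.

    Same structure as the full historical design but with a configurable
    adult size cap and a two-step juvenile chain
    (seed -> protocorm -> seedling -> adult entry).
    """
    return _historical_space(max_size=max_size, juvenile_plan="toy", entry_names=entry_names)


def historical_space(max_size: int, entry_names: tuple[str, ...],
                     juvenile_plan: str = "cypripedium") -> StateSpace:
    """General constructor with overridable entry stages (config hook)."""
    return _historical_space(max_size, juvenile_plan, entry_names)


def agestage_space(
    max_size: int = 8,
    max_age: int = 10,
    entry_names: tuple[str, ...] = ("D", "V1", "V2"),
) -> StateSpace:
    """Age x stage space: juvenile chain plus ``max_age`` adult age classes
    of ``2 * max_size + 1`` mature states, with stasis at the final age."""
    mats = mature_stages(max_size)
    by_name = {s.name: s for s in mats}
    entries = [by_name[n] for n in entry_names]

    labels: list[str] = []
    curr: list[Stage] = []
    ages: list[int] = []

    def add(stage: Stage, age: int) -> int:
        labels.append(f"a{age}|{stage.name}" if age else stage.name)
        curr.append(stage)
        ages.append(age)
        return len(labels) - 1

    p1 = Stage("P1", PROTOCORM)
    p2 = Stage("P2", PROTOCORM)
    sdl = Stage("SDL", SEEDLING, 1)
    i_p1 = add(p1, 0)
    i_p2 = add(p2, 0)
    i_sdl = add(sdl, 0)

    pair_index: dict = {}
    for a in range(1, max_age + 1):
        for s in mats:
            pair_index[(a, s.name)] = add(s, a)

    nondorm = [k for k, e in enumerate(entries) if not e.dormant]
    dorm = next(k for k, e in enumerate(entries) if e.dormant)
    jcols = [
        JuvenileColumn(i_p1, "p1", (i_p2,), (1.0,)),
        JuvenileColumn(i_p2, "protocorm_to_seedling", (i_sdl,), (1.0,)),
        JuvenileColumn(
            i_sdl, "sdl",
            targets=tuple(pair_index[(1, entries[k].name)] for k in nondorm),
            weights=tuple(f"entry_{entries[k].name}" for k in nondorm),
            sprout_key="entry_sprout",
            dormant_target=pair_index[(1, entries[dorm].name)],
        ),
    ]
    space = StateSpace(
        kind="agestage",
        labels=labels,
        curr_stage=curr,
        prev_stage=[None] * len(labels),
        age=ages,
        max_size=max_size,
        max_age=max_age,
        mature=mats,
        juvenile_columns=jcols,
        fecundity_target=i_p1,
        founder_index=pair_index[(1, entries[nondorm[0]].name)],
        entry_stages=entries,
    )
    space._adult_pair_index = pair_index
    return space


def ophrys_state_space() -> StateSpace:
    """Age x stage space for the *Ophrys* design: 10 adult age classes of
    17 mature states (1..8 leaves vegetative or flowering, plus dormancy)
    with stasis at age 10, plus two protocorm stages and one seedling
    stage -- 173 states."""
    return agestage_space(max_size=8, max_age=10, entry_names=("D", "V1", "V2"))


def toy_agestage_space(max_size: int = 3, max_age: int = 4) -> StateSpace:
    """Small age x stage space for tests."""
    return agestage_space(max_size=max_size, max_age=max_age, entry_names=("D", "V1", "V2"))


def default_juvenile_params(space: StateSpace) -> dict[str, float]:
    """Literature-style default juvenile transition probabilities.

    These parametrize the unmonitored subterranean stages (protocorm
    survival, seedling emergence, adult entry-stage mix).  They are
    configuration defaults, not constants: callers override any subset.
    Entry weights are conditional on emergence and must sum to 1 over the
    non-dormant entry stages.
    """
    params = {
        "p1": 0.45,
        "p2": 0.50,
        "ns": 0.60,
        "s1": 0.65,
        "s2": 0.70,
        "sdl": 0.60,
        "seedling_sprout": 0.70,
        "entry_sprout": 0.80,
        "one_sprout": 0.80,
        "two_sprout": 0.20,
    }
    nondorm = [e for e in space.entry_stages if not e.dormant]
    base = {2: (0.7, 0.3), 3: (0.6, 0.3, 0.1), 5: (0.5, 0.25, 0.1, 0.05, 0.1)}
    weights = base.get(len(nondorm))
    if weights is None:
        weights = tuple(1.0 / len(nondorm) for _ in nondorm)
    for e, w in zip(nondorm, weights):
        params[f"entry_{e.name}"] = w
    return params


def admissible_arcs(space: StateSpace) -> set[tuple[int, int, str]]:
    """Enumerate the structurally admissible arcs of a space.

    Returns ``(target_row, source_col, kind)`` triples with kind
    ``"transition"`` or ``"fecundity"``.  For historical spaces, a
    transition from pair ``(i, j)`` may only target pairs ``(j, k)``
    (chaining rule); for age x stage spaces transitions increment age (or
    hold at the final class).  Fecundity arcs run from every state whose
    current stage is flowering to the first juvenile state.
    """
    if space.kind not in ("historical", "agestage"):
        raise InvalidArgumentError(f"malformed space kind {space.kind!r}")
    arcs: set[tuple[int, int, str]] = set()
    for col in range(space.n):
        if space.curr_stage[col].mature:
            d, tv, tf = space.adult_targets(col)
            arcs.add((d, col, "transition"))
            for t in list(tv) + list(tf):
                arcs.add((int(t), col, "transition"))
    for jc in space.juvenile_columns:
        for t in jc.targets:
            arcs.add((int(t), jc.index, "transition"))
        if jc.dormant_target is not None:
            arcs.add((int(jc.dormant_target), jc.index, "transition"))
    for col in np.flatnonzero(space.is_flowering):
        arcs.add((space.fecundity_target, int(col), "fecundity"))
    return arcs
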