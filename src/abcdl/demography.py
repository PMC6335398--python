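"""Competing demographic models of archaic introgression in Eurasia and Oceania.

Eight models (labelled ``A`` .. ``H``) share a modern-human backbone — an
Out-of-Africa split, a European / Asia-Pacific split, an Asian clade (East
Asian, Andamanese, Indian) and an Oceanian clade (Papuan, Australian), plus
Neanderthal and Denisovan archaic branches and a deep *Homo erectus*-like
ghost (Xd) that introgresses into Denisovans.  All models carry a Neanderthal
pulse into the Out-of-Africa ancestor and a Denisovan pulse into the Oceanian
ancestor, and recent continuous migration between African/European,
European/East-Asian and Papuan/Australian pairs.  They differ only in the
extra introgression scheme:

* ``A`` — backbone only.
* ``B`` — a non-introgressed "basal Eurasian" modern ghost (Xn) admixing
  into Europeans.
* ``C`` — a second Neanderthal pulse into the Asia-Pacific ancestor.
* ``D`` — a second Denisovan pulse into the Asia-Pacific ancestor.
* ``E``/``F``/``G``/``H`` — an archaic ghost (Xe) pulsing into the
  Asia-Pacific ancestor, with Xe a Neanderthal sister (E), a Denisovan
  sister (F), an outgroup of both (G), or a Neanderthal-Denisovan admixture
  product (H).  E and F are the H model with the Denisovan fraction of the
  Xe origin pinned to 0 and 1 respectively.

Times are handled internally in generations; configuration in years is
converted at 29 years per generation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GENERATION_TIME_YEARS",
    "MODEL_LABELS",
    "PopulationLabel",
    "Prior",
    "DemographicEvent",
    "DemographicModel",
    "ParameterVector",
    "SimEvent",
    "SimulatorSpec",
    "build_model",
    "sample_parameters",
    "to_simulator_spec",
    "posterior_means",
    "model_to_dict",
    "model_from_dict",
    "model_to_yaml",
    "model_from_yaml",
]

GENERATION_TIME_YEARS = 29.0
MODEL_LABELS = "ABCDEFGH"

#: sampled populations present in every model, in canonical axis order
SAMPLED_POPULATIONS = ("AFR", "EUR", "ASN", "AND", "IND", "PAP", "AUS", "NEAN", "DENI")
GHOSTS = ("Xe", "Xn", "Xd")
#: internal ancestor containers emitted by the simulator adapter
ANCESTORS = ("PACIFIC", "ASIA", "ASIAPAC", "EURASIA", "AMH", "ND", "HOMININ", "ROOT")


def kya_to_gen(kya: float) -> float:
    """Convert thousands of years to generations at 29 years/generation."""
    return kya * 1000.0 / GENERATION_TIME_YEARS


def gen_to_kya(gen: float) -> float:
    return gen * GENERATION_TIME_YEARS / 1000.0


@dataclass(frozen=True)
class PopulationLabel:
    """A population in a demographic model.

    ``sampling_time`` is in generations before present; modern populations
    are sampled at 0, archaic sampling ages are configurable.
    """

    code: str
    sampled: bool
    sampling_time: float = 0.0


@dataclass(frozen=True)
class Prior:
    """Marginal prior for one scalar parameter.

    families: ``uniform``/``log_uniform`` use (low, high); ``normal`` uses
    (mean, sd); ``fixed`` uses ``value``.  ``units`` is one of
    ``generations``, ``size`` (diploid effective size), ``proportion`` or
    ``rate`` (migrants per generation).
    """

    name: str
    family: str
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    sd: float | None = None
    value: float | None = None
    units: str = "generations"

    def __post_init__(self) -> None:
        if self.family not in {"uniform", "log_uniform", "normal", "fixed"}:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family in {"uniform", "log_uniform"}:
            if self.low is None or self.high is None or self.low > self.high:
                raise ValueError(f"prior {self.name}: need low <= high")
            if self.family == "log_uniform" and self.low <= 0:
                raise ValueError(f"prior {self.name}: log_uniform needs low > 0")
        if self.family == "normal" and (self.mean is None or self.sd is None or self.sd < 0):
            raise ValueError(f"prior {self.name}: need mean and sd >= 0")
        if self.family == "fixed" and self.value is None:
            raise ValueError(f"prior {self.name}: fixed prior needs a value")
        if self.units == "proportion":
            lo = self.low if self.low is not None else self.value
            hi = self.high if self.high is not None else self.value
            if lo is not None and hi is not None and (lo < 0 or hi > 1):
                raise ValueError(f"prior {self.name}: proportions must stay in [0,1]")

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return float(self.value)
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.family == "log_uniform":
            return float(math.exp(rng.uniform(math.log(self.low), math.log(self.high))))
        return float(rng.normal(self.mean, self.sd))


@dataclass(frozen=True)
class DemographicEvent:
    """One structural element of a model, in forward-time phrasing.

    kinds:
      ``split``               sources (children) coalesce into ``dest``
                              (their common ancestor) at ``time_param``;
                              a single source joining an already-live branch
                              is a lineage merge.
      ``pulse_admixture``     sources[0] donates ``fraction_param`` of the
                              ancestry of ``dest`` at ``time_param``.
      ``admixed_origin``      ``dest`` originates at ``time_param`` as a mix
                              of sources (exactly two); ``fraction_param``
                              is the fraction from sources[1].
      ``continuous_migration`` symmetric migration between sources[0] and
                              dest at rate ``fraction_param``, from the
                              present until the pair merges.
    """

    kind: str
    time_param: str | None
    sources: tuple[str, ...]
    dest: str
    fraction_param: str | float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"split", "pulse_admixture", "admixed_origin",
                             "continuous_migration", "size_change"}:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "admixed_origin" and len(self.sources) != 2:
            raise ValueError("admixed_origin needs exactly two sources")


class ParameterVector(dict):
    """One named draw of all parameters of a model (a plain mapping)."""

    def __init__(self, model_label: str, values: Mapping[str, float]):
        super().__init__(values)
        self.model_label = model_label


@dataclass
class DemographicModel:
    label: str
    populations: list[PopulationLabel]
    events: list[DemographicEvent]
    priors: dict[str, Prior]
    #: pairs (a, b) meaning value[a] < value[b] must hold
    constraints: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.validate()

    # -- structure checks -------------------------------------------------
    def parameter_names(self) -> list[str]:
        return list(self.priors)

    def referenced_parameters(self) -> set[str]:
        out: set[str] = set()
        for ev in self.events:
            if ev.time_param is not None:
                out.add(ev.time_param)
            if isinstance(ev.fraction_param, str):
                out.add(ev.fraction_param)
        return out

    def validate(self) -> None:
        ghosts = {p.code for p in self.populations if p.code in GHOSTS}
        for p in self.populations:
            if p.code in GHOSTS and p.sampled:
                raise ValueError(f"ghost population {p.code} cannot be sampled")
        sampled = [p.code for p in self.populations if p.sampled]
        if len(sampled) != 9:
            raise ValueError(f"expected 9 sampled populations, got {len(sampled)}")
        missing = self.referenced_parameters() - set(self.priors)
        if missing:
            raise ValueError(f"events reference parameters without priors: {sorted(missing)}")
        # ordering-constraint graph must be acyclic
        order: dict[str, set[str]] = {}
        for a, b in self.constraints:
            order.setdefault(a, set()).add(b)
        seen: dict[str, int] = {}

        def dfs(u: str) -> None:
            seen[u] = 1
            for v in order.get(u, ()):
                if seen.get(v) == 1:
                    raise ValueError("constraint graph has a cycle")
                if v not in seen:
                    dfs(v)
            seen[u] = 2

        for u in list(order):
            if u not in seen:
                dfs(u)

    def satisfies_constraints(self, params: Mapping[str, float]) -> bool:
        return all(params[a] < params[b] for a, b in self.constraints)


# ---------------------------------------------------------------------------
# default priors
# ---------------------------------------------------------------------------

def _t(name: str, lo_kya: float, hi_kya: float) -> Prior:
    return Prior(name, "log_uniform", low=kya_to_gen(lo_kya), high=kya_to_gen(hi_kya),
                 units="generations")


def _frac(name: str, hi: float = 0.2) -> Prior:
    return Prior(name, "uniform", low=0.0, high=hi, units="proportion")


def _size(name: str) -> Prior:
    return Prior(name, "log_uniform", low=100.0, high=100_000.0, units="size")


def _mig(name: str) -> Prior:
    return Prior(name, "log_uniform", low=1e-6, high=1e-3, units="rate")


def _backbone_priors() -> dict[str, Prior]:
    priors = [
        _t("t_pap_aus", 10, 60),
        _t("t_ea_an_i", 12, 60),
        _t("t_asia_pacific", 20, 80),
        _t("t_e_asia_pacific", 30, 100),
        _t("t_eurasia_a", 50, 250),
        _t("t_n_d", 150, 700),
        _t("t_hominin", 250, 1000),
        _t("t_hominin_er", 600, 2000),
        _t("t_intro_d_pac", 15, 70),
        _frac("f_intro_d_pac"),
        _t("t_intro_n_ooa", 35, 150),
        _frac("f_intro_n_ooa"),
        _t("t_intro_xd_d", 20, 150),
        _frac("f_intro_xd_d"),
    ]
    priors += [_size(f"n_{p.lower()}") for p in SAMPLED_POPULATIONS]
    priors += [_size("n_xd"), _size("n_ooa"), _size("n_anc"), _size("n_arch")]
    priors += [_mig("m_afr_eur"), _mig("m_eur_asn"), _mig("m_pap_aus")]
    return {p.name: p for p in priors}


_BACKBONE_CONSTRAINTS: list[tuple[str, str]] = [
    ("t_pap_aus", "t_intro_d_pac"),
    ("t_intro_d_pac", "t_asia_pacific"),
    ("t_ea_an_i", "t_asia_pacific"),
    ("t_asia_pacific", "t_e_asia_pacific"),
    ("t_e_asia_pacific", "t_intro_n_ooa"),
    ("t_intro_n_ooa", "t_eurasia_a"),
    ("t_eurasia_a", "t_n_d"),
    ("t_intro_xd_d", "t_n_d"),
    ("t_n_d", "t_hominin"),
    ("t_hominin", "t_hominin_er"),
]


def _backbone_events() -> list[DemographicEvent]:
    E = DemographicEvent
    return [
        E("continuous_migration", None, ("AFR",), "EUR", "m_afr_eur"),
        E("continuous_migration", None, ("EUR",), "ASN", "m_eur_asn"),
        E("continuous_migration", None, ("PAP",), "AUS", "m_pap_aus"),
        E("split", "t_pap_aus", ("PAP", "AUS"), "PACIFIC"),
        E("split", "t_ea_an_i", ("ASN", "AND", "IND"), "ASIA"),
        E("pulse_admixture", "t_intro_d_pac", ("DENI",), "PACIFIC", "f_intro_d_pac"),
        E("split", "t_asia_pacific", ("ASIA", "PACIFIC"), "ASIAPAC"),
        E("split", "t_e_asia_pacific", ("EUR", "ASIAPAC"), "EURASIA"),
        E("pulse_admixture", "t_intro_n_ooa", ("NEAN",), "EURASIA", "f_intro_n_ooa"),
        E("pulse_admixture", "t_intro_xd_d", ("Xd",), "DENI", "f_intro_xd_d"),
        E("split", "t_eurasia_a", ("AFR", "EURASIA"), "AMH"),
        E("split", "t_n_d", ("NEAN", "DENI"), "ND"),
        E("split", "t_hominin", ("AMH", "ND"), "HOMININ"),
        E("split", "t_hominin_er", ("HOMININ", "Xd"), "ROOT"),
    ]


def _xe_events(origin_kind: str) -> list[DemographicEvent]:
    """Xe pulse plus its origin event; origin_kind is 'admixed' (E/F/H) or
    'outgroup' (G)."""
    E = DemographicEvent
    events = [E("pulse_admixture", "t_intro_xe_asiapac", ("Xe",), "ASIAPAC",
                "f_intro_xe_asiapac")]
    if origin_kind == "admixed":
        events.append(E("admixed_origin", "t_xe_origin", ("NEAN", "DENI"), "Xe",
                        "f_admix_d"))
    else:
        events.append(E("split", "t_xe_origin", ("Xe",), "ND"))
    return events


def build_model(label: str, config: Mapping[str, object] | None = None) -> DemographicModel:
    """Build one of the eight demographic models.

    Parameters
    ----------
    label:
        Model letter ``A`` .. ``H``.
    config:
        Optional overrides: ``priors`` maps parameter names to :class:`Prior`
        (or dicts accepted by :class:`Prior`); ``archaic_sampling_age`` sets
        the sampling time (generations) of the Neanderthal and Denisovan
        individuals (default 0, i.e. co-sampled with moderns).
    """
    if label not in MODEL_LABELS:
        raise ValueError(f"unknown model label {label!r}; expected one of {MODEL_LABELS}")
    config = dict(config or {})
    archaic_age = float(config.pop("archaic_sampling_age", 0.0))
    prior_overrides = config.pop("priors", {})
    if config:
        raise ValueError(f"unknown config keys {sorted(config)}")

    priors = _backbone_priors()
    constraints = list(_BACKBONE_CONSTRAINTS)
    events = _backbone_events()
    ghost_codes = ["Xd"]

    if label == "B":
        ghost_codes.append("Xn")
        events += [
            DemographicEvent("pulse_admixture", "t_admix_xn_eur", ("Xn",), "EUR",
                             "f_admix_xn_eur"),
            DemographicEvent("split", "t_xn_split", ("Xn",), "EURASIA"),
        ]
        priors.update({p.name: p for p in [
            _t("t_xn_split", 40, 200),
            _t("t_admix_xn_eur", 5, 50),
            _frac("f_admix_xn_eur", 0.5),
            _size("n_xn"),
        ]})
        constraints += [
            ("t_intro_n_ooa", "t_xn_split"),
            ("t_xn_split", "t_eurasia_a"),
            ("t_admix_xn_eur", "t_e_asia_pacific"),
        ]
    elif label == "C":
        events.append(DemographicEvent("pulse_admixture", "t_intro_n2_asia", ("NEAN",),
                                       "ASIAPAC", "f_intro_n2_asia"))
        priors.update({p.name: p for p in [_t("t_intro_n2_asia", 25, 90),
                                           _frac("f_intro_n2_asia")]})
        constraints += [("t_asia_pacific", "t_intro_n2_asia"),
                        ("t_intro_n2_asia", "t_e_asia_pacific")]
    elif label == "D":
        events.append(DemographicEvent("pulse_admixture", "t_intro_d2_asia", ("DENI",),
                                       "ASIAPAC", "f_intro_d2_asia"))
        priors.update({p.name: p for p in [_t("t_intro_d2_asia", 25, 90),
                                           _frac("f_intro_d2_asia")]})
        constraints += [("t_asia_pacific", "t_intro_d2_asia"),
                        ("t_intro_d2_asia", "t_e_asia_pacific")]
    elif label in "EFGH":
        ghost_codes.append("Xe")
        events += _xe_events("outgroup" if label == "G" else "admixed")
        priors.update({p.name: p for p in [
            _t("t_intro_xe_asiapac", 25, 90),
            _frac("f_intro_xe_asiapac"),
            _size("n_xe"),
        ]})
        constraints += [("t_asia_pacific", "t_intro_xe_asiapac"),
                        ("t_intro_xe_asiapac", "t_e_asia_pacific"),
                        ("t_intro_xe_asiapac", "t_xe_origin")]
        if label == "G":
            priors["t_xe_origin"] = _t("t_xe_origin", 150, 1000)
            constraints += [("t_n_d", "t_xe_origin"), ("t_xe_origin", "t_hominin")]
        else:
            priors["t_xe_origin"] = _t("t_xe_origin", 100, 600)
            constraints += [("t_xe_origin", "t_n_d")]
            if label == "E":
                priors["f_admix_d"] = Prior("f_admix_d", "fixed", value=0.0,
                                            units="proportion")
            elif label == "F":
                priors["f_admix_d"] = Prior("f_admix_d", "fixed", value=1.0,
                                            units="proportion")
            else:  # H
                priors["f_admix_d"] = Prior("f_admix_d", "uniform", low=0.0, high=1.0,
                                            units="proportion")

    for name, override in dict(prior_overrides).items():
        if name not in priors:
            raise ValueError(f"prior override for unknown parameter {name!r} in model {label}")
        if isinstance(override, Prior):
            priors[name] = override
        elif isinstance(override, Mapping):
            priors[name] = Prior(name=name, **{k: v for k, v in override.items() if k != "name"})
        else:
            priors[name] = Prior(name, "fixed", value=float(override),
                                 units=priors[name].units)

    populations = [PopulationLabel(c, True, archaic_age if c in ("NEAN", "DENI") else 0.0)
                   for c in SAMPLED_POPULATIONS]
    populations += [PopulationLabel(c, False) for c in ghost_codes]
    return DemographicModel(label, populations, events, priors, constraints)


def sample_parameters(model: DemographicModel, rng: np.random.Generator,
                      max_tries: int = 100_000) -> ParameterVector:
    """Draw one parameter vector from the joint prior.

    Ordering constraints are enforced by rejection resampling of the whole
    vector (no clipping), so marginals conditional on the constraints are
    exact.
    """
    for _ in range(max_tries):
        values = {name: prior.draw(rng) for name, prior in model.priors.items()}
        if model.satisfies_constraints(values):
            return ParameterVector(model.label, values)
    raise RuntimeError(f"constraints of model {model.label} unsatisfiable "
                       f"within {max_tries} draws")


# ---------------------------------------------------------------------------
# simulator-neutral spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimEvent:
    """A resolved, numeric event (times in generations before present)."""

    time: float
    op: str           # split | pulse | admixed_origin | migration
    args: tuple

    def to_dict(self) -> dict:
        return {"time": self.time, "op": self.op, "args": list(self.args)}


@dataclass
class SimulatorSpec:
    """Everything a coalescent engine needs: populations with sizes and
    sampling times, plus a time-ordered event list (most recent first)."""

    model_label: str
    populations: list[tuple[str, float, float, bool]]  # (name, size, sampling_time, sampled)
    events: list[SimEvent]

    def to_dict(self) -> dict:
        return {"model_label": self.model_label,
                "populations": [list(p) for p in self.populations],
                "events": [e.to_dict() for e in self.events]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulatorSpec":
        return cls(d["model_label"],
                   [tuple(p) for p in d["populations"]],
                   [SimEvent(e["time"], e["op"], tuple(e["args"])) for e in d["events"]])


_ANCESTOR_SIZE_PARAM = {
    "PACIFIC": "n_ooa", "ASIA": "n_ooa", "ASIAPAC": "n_ooa", "EURASIA": "n_ooa",
    "AMH": "n_anc", "HOMININ": "n_anc", "ROOT": "n_anc", "ND": "n_arch",
}


def _resolve(params: Mapping[str, float], ref: str | float | None) -> float:
    if isinstance(ref, str):
        return float(params[ref])
    return float(ref) if ref is not None else 0.0


def to_simulator_spec(model: DemographicModel, params: Mapping[str, float]) -> SimulatorSpec:
    """Translate a model plus a parameter draw into a numeric event list.

    The translation is deterministic; pulses with fraction exactly 0 are
    pruned (identical to absence of the event).  Events are sorted by time
    ascending (oldest last), with structural order as tie-break.
    """
    if isinstance(params, ParameterVector) and params.model_label != model.label:
        raise ValueError("parameter vector was drawn from a different model")
    if not model.satisfies_constraints(params):
        raise ValueError("parameter vector violates model constraints")

    pops: list[tuple[str, float, float, bool]] = []
    for p in model.populations:
        size_param = f"n_{p.code.lower()}"
        pops.append((p.code, float(params[size_param]), p.sampling_time, p.sampled))
    needed_ancestors = {ev.dest for ev in model.events if ev.kind == "split"}
    for anc in ANCESTORS:
        if anc in needed_ancestors:
            pops.append((anc, float(params[_ANCESTOR_SIZE_PARAM[anc]]), 0.0, False))

    sample_times = {p.code: p.sampling_time for p in model.populations if p.sampled}
    events: list[SimEvent] = []
    for ev in model.events:
        t = _resolve(params, ev.time_param) if ev.time_param is not None else 0.0
        if ev.kind == "continuous_migration":
            rate = _resolve(params, ev.fraction_param)
            events.append(SimEvent(0.0, "migration", (ev.sources[0], ev.dest, rate)))
            continue
        for code, st in sample_times.items():
            if code in ev.sources or code == ev.dest:
                if t <= st:
                    raise ValueError(
                        f"event at {t:.1f} gen conflicts with sampling time "
                        f"{st:.1f} of {code}")
        if ev.kind == "split":
            events.append(SimEvent(t, "split", (tuple(ev.sources), ev.dest)))
        elif ev.kind == "pulse_admixture":
            frac = _resolve(params, ev.fraction_param)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"pulse fraction {frac} outside [0,1]")
            if frac == 0.0:
                continue  # pruned: identical to absence of the event
            events.append(SimEvent(t, "pulse", (ev.dest, ev.sources[0], frac)))
        elif ev.kind == "admixed_origin":
            frac = _resolve(params, ev.fraction_param)
            events.append(SimEvent(t, "admixed_origin",
                                   (ev.dest, tuple(ev.sources), (1.0 - frac, frac))))
        else:
            raise ValueError(f"cannot translate event kind {ev.kind}")
    order = {id(e): i for i, e in enumerate(events)}
    events.sort(key=lambda e: (e.time, order[id(e)]))
    return SimulatorSpec(model.label, pops, events)


# ---------------------------------------------------------------------------
# point estimates (posterior means) and fixed defaults
# ---------------------------------------------------------------------------

#: documented default point sizes (diploid) used when simulating at posterior
#: means; drawn from standard human-demography literature values.
DEFAULT_POINT_SIZES = {
    "n_afr": 24_000, "n_eur": 10_000, "n_asn": 10_000, "n_and": 5_000,
    "n_ind": 10_000, "n_pap": 5_000, "n_aus": 5_000, "n_nean": 2_500,
    "n_deni": 2_500, "n_xe": 2_500, "n_xd": 5_000, "n_xn": 5_000,
    "n_ooa": 5_000, "n_anc": 15_000, "n_arch": 3_000,
}
DEFAULT_POINT_MIGRATION = 2.5e-5

#: posterior-mean times (kya) and fractions for the admixture-origin model (H)
#: and its Denisova-sister variant (F); shared backbone entries reused for the
#: other labels with documented defaults for their extra parameters.
_POSTERIOR_MEANS_KYA_H = {
    "t_pap_aus": 31.88, "t_ea_an_i": 39.54, "t_asia_pacific": 46.95,
    "t_e_asia_pacific": 57.85, "t_eurasia_a": 121.38, "t_n_d": 314.07,
    "t_hominin": 558.22, "t_hominin_er": 1492.86,
    "t_intro_d_pac": 43.10, "t_intro_xd_d": 77.90,
    "t_intro_xe_asiapac": 51.03, "t_intro_n_ooa": 69.47,
    "t_xe_origin": 304.41,
}
_POSTERIOR_MEANS_FRAC_H = {
    "f_intro_d_pac": 0.016, "f_intro_xd_d": 0.013, "f_intro_xe_asiapac": 0.026,
    "f_intro_n_ooa": 0.013, "f_admix_d": 0.511,
}
_POSTERIOR_MEANS_KYA_F = {
    "t_pap_aus": 31.37, "t_ea_an_i": 37.77, "t_asia_pacific": 47.60,
    "t_e_asia_pacific": 56.60, "t_eurasia_a": 137.68, "t_n_d": 320.25,
    "t_hominin": 531.23, "t_hominin_er": 1474.61,
    "t_intro_d_pac": 43.12, "t_intro_xd_d": 68.02,
    "t_intro_xe_asiapac": 53.73, "t_intro_n_ooa": 77.49,
    "t_xe_origin": 279.16,
}
_POSTERIOR_MEANS_FRAC_F = {
    "f_intro_d_pac": 0.016, "f_intro_xd_d": 0.011, "f_intro_xe_asiapac": 0.034,
    "f_intro_n_ooa": 0.019, "f_admix_d": 1.0,
}
#: defaults for parameters specific to models B/C/D/E/G (no published means)
_EXTRA_POINT_DEFAULTS_KYA = {
    "t_xn_split": 100.0, "t_admix_xn_eur": 30.0,
    "t_intro_n2_asia": 50.0, "t_intro_d2_asia": 50.0,
}
_EXTRA_POINT_DEFAULTS_FRAC = {
    "f_admix_xn_eur": 0.10, "f_intro_n2_asia": 0.01, "f_intro_d2_asia": 0.01,
}


def posterior_means(label: str) -> ParameterVector:
    """Point parameter vector (posterior means) for a model label.

    Models H and F use their published posterior means; the other labels
    reuse the shared backbone means of model H with documented defaults for
    their model-specific parameters.  Effective sizes and migration rates use
    :data:`DEFAULT_POINT_SIZES` / :data:`DEFAULT_POINT_MIGRATION`.
    """
    model = build_model(label)
    kya = dict(_POSTERIOR_MEANS_KYA_F if label == "F" else _POSTERIOR_MEANS_KYA_H)
    frac = dict(_POSTERIOR_MEANS_FRAC_F if label == "F" else _POSTERIOR_MEANS_FRAC_H)
    kya.update(_EXTRA_POINT_DEFAULTS_KYA)
    frac.update(_EXTRA_POINT_DEFAULTS_FRAC)
    if label == "E":
        frac["f_admix_d"] = 0.0
    if label == "G":
        kya["t_xe_origin"] = 436.0  # between the archaic split and the hominin root
    values: dict[str, float] = {}
    for name in model.priors:
        if name in kya:
            values[name] = kya_to_gen(kya[name])
        elif name in frac:
            values[name] = frac[name]
        elif name in DEFAULT_POINT_SIZES:
            values[name] = float(DEFAULT_POINT_SIZES[name])
        elif name.startswith("m_"):
            values[name] = DEFAULT_POINT_MIGRATION
        else:
            raise KeyError(f"no point default for parameter {name}")
    pv = ParameterVector(label, values)
    if not model.satisfies_constraints(pv):
        raise RuntimeError(f"point estimates violate constraints of model {label}")
    return pv


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: DemographicModel) -> dict:
    return {
        "label": model.label,
        "populations": [dataclasses.asdict(p) for p in model.populations],
        "events": [dataclasses.asdict(e) | {"sources": list(e.sources)}
                   for e in model.events],
        "priors": {n: {k: v for k, v in dataclasses.asdict(p).items() if v is not None}
                   for n, p in model.priors.items()},
        "constraints": [list(c) for c in model.constraints],
    }


def model_from_dict(d: Mapping) -> DemographicModel:
    return DemographicModel(
        label=d["label"],
        populations=[PopulationLabel(**p) for p in d["populations"]],
        events=[DemographicEvent(kind=e["kind"], time_param=e["time_param"],
                                 sources=tuple(e["sources"]), dest=e["dest"],
                                 fraction_param=e.get("fraction_param"))
                for e in d["events"]],
        priors={n: Prior(**p) for n, p in d["priors"].items()},
        constraints=[tuple(c) for c in d["constraints"]],
    )


def model_to_yaml(model: DemographicModel) -> str:
    return yaml.safe_dump(model_to_dict(model), sort_keys=False)


def model_from_yaml(text: str) -> DemographicModel:
    return model_from_dict(yaml.safe_load(text))
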