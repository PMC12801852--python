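"""The two-refugium origin-scenario catalogue: 6 split + 9 vicariance models.

A *split* scenario derives one region's population from an expansion of a
fraction of the other's (the origin), with minimal or no change in the
origin's size at the divergence: backward in time the derived population
merges into the origin at T and the ancestral size equals the origin's
size at divergence.  A *vicariance* scenario assumes the ancestral
population's size is the sum of the two daughter sizes at divergence.
Options layer optional bidirectional gene flow and post-divergence
bottlenecks onto either family.

Populations are indexed 0 = SEA, 1 = NEA.  Divergence/bottleneck times
are parameterized in ka and converted to coalescent units (4*N_ref
generations) at compile time using the configured generation time.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .calibrate import ka_to_coalescent_time
from .coalsim import DemographicEvent, DemographyProgram

POP_INDEX = {"SEA": 0, "NEA": 1}
DEFAULT_N_REF = 10_000.0
DEFAULT_GENERATION_TIME = 15.0


@dataclass(frozen=True)
class Prior:
    dist: str  # 'uniform' | 'loguniform' | 'point'
    low: float
    high: float | None = None

    def __post_init__(self) -> None:
        if self.dist == "point":
            return
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if self.high is None or self.low >= self.high:
            raise ValueError("prior requires low < high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("loguniform prior requires positive bounds")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "point":
            return self.low
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.low, self.low if self.high is None else self.high)


def default_priors() -> dict[str, Prior]:
    return {
        "T": Prior("uniform", 50.0, 1500.0),
        "T_SEA": Prior("uniform", 10.0, 1500.0),
        "T_NEA": Prior("uniform", 10.0, 1500.0),
        "N_SEA": Prior("loguniform", 1e2, 1e5),
        "N_NEA": Prior("loguniform", 1e2, 1e5),
        "N_SEA_b": Prior("loguniform", 1e2, 1e5),
        "N_NEA_b": Prior("loguniform", 1e2, 1e5),
        "f": Prior("uniform", 0.01, 1.0),
        "Nm_SEA_NEA": Prior("loguniform", 1e-3, 10.0),
        "Nm_NEA_SEA": Prior("loguniform", 1e-3, 10.0),
    }


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    family: str                       # 'split' | 'vicariance'
    origin_pop: str                   # 'SEA' | 'NEA' | 'none'
    gene_flow: str                    # 'none' | 'bidirectional'
    bottlenecks: str                  # 'none' | 'SEA' | 'NEA' | 'both' | 'derived'
    priors: dict[str, Prior] = field(default_factory=dict, hash=False, compare=False)
    equal_sizes: bool = False         # N_NEA constrained equal to N_SEA
    n_ref: float = DEFAULT_N_REF
    generation_time: float = DEFAULT_GENERATION_TIME

    def free_parameters(self) -> list[str]:
        params = ["T", "N_SEA", "N_NEA"]
        if self.equal_sizes:
            params.remove("N_NEA")
        if self.family == "split":
            params.append("f")
        if self.gene_flow == "bidirectional":
            params += ["Nm_SEA_NEA", "Nm_NEA_SEA"]
        bn = self._bottleneck_pops()
        for region in bn:
            params.append(f"T_{region}")
            # in split scenarios the derived pop's bottleneck size is the
            # founder size f*N_anc, not a free parameter
            if not (self.family == "split" and region != self.origin_pop):
                params.append(f"N_{region}_b")
        return params

    def _bottleneck_pops(self) -> list[str]:
        if self.bottlenecks == "none":
            return []
        if self.bottlenecks == "both":
            return ["SEA", "NEA"]
        if self.bottlenecks == "derived":
            return [r for r in POP_INDEX if r != self.origin_pop]
        return [self.bottlenecks]

    def to_config(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "family": self.family,
            "origin_pop": self.origin_pop,
            "gene_flow": self.gene_flow,
            "bottlenecks": self.bottlenecks,
            "equal_sizes": self.equal_sizes,
            "n_ref": self.n_ref,
            "generation_time": self.generation_time,
            "priors": {
                k: {"dist": p.dist, "low": p.low, "high": p.high}
                for k, p in self.priors.items()
            },
        }


@dataclass
class ScenarioDraw:
    scenario_id: str
    params: dict[str, float]
    program: DemographyProgram


def _with_priors(spec: ScenarioSpec, overrides: dict[str, Prior] | None) -> ScenarioSpec:
    priors = default_priors()
    if overrides:
        priors.update(overrides)
    priors = {k: priors[k] for k in spec.free_parameters()}
    return ScenarioSpec(**{**spec.__dict__, "priors": priors})


def build_split_scenario(origin_pop: str, gene_flow: str = "none",
                         bottlenecks: str = "none",
                         priors: dict[str, Prior] | None = None,
                         scenario_id: str | None = None) -> ScenarioSpec:
    """A split-family scenario: `origin_pop` is ancestral, the other derived."""
    if origin_pop not in POP_INDEX:
        raise ValueError("origin_pop must be 'SEA' or 'NEA'")
    if bottlenecks not in ("none", "both", "derived", "SEA", "NEA"):
        raise ValueError(f"unknown bottleneck option {bottlenecks!r}")
    if gene_flow not in ("none", "bidirectional"):
        raise ValueError(f"unknown gene_flow option {gene_flow!r}")
    sid = scenario_id or _split_id(origin_pop, gene_flow, bottlenecks)
    spec = ScenarioSpec(sid, "split", origin_pop, gene_flow, bottlenecks)
    return _with_priors(spec, priors)


def build_vicariance_scenario(gene_flow: str = "none", bottlenecks: str = "none",
                              equal_sizes: bool = False,
                              priors: dict[str, Prior] | None = None,
                              scenario_id: str | None = None) -> ScenarioSpec:
    """A vicariance-family scenario: N_anc = sum of the two sizes at divergence."""
    if bottlenecks not in ("none", "both", "SEA", "NEA"):
        raise ValueError(f"unknown bottleneck option {bottlenecks!r}")
    if gene_flow not in ("none", "bidirectional"):
        raise ValueError(f"unknown gene_flow option {gene_flow!r}")
    sid = scenario_id or _vic_id(gene_flow, bottlenecks, equal_sizes)
    spec = ScenarioSpec(sid, "vicariance", "none", gene_flow, bottlenecks,
                        equal_sizes=equal_sizes)
    return _with_priors(spec, priors)


def _split_id(origin, flow, bn):
    parts = [f"SPLIT_{origin}_ORIGIN"]
    if flow != "none":
        parts.append("FLOW")
    if bn != "none":
        parts.append(f"BN_{bn.upper()}")
    return "_".join(parts)


def _vic_id(flow, bn, equal):
    parts = ["VIC"]
    if equal:
        parts.append("EQUALSIZE")
    if flow != "none":
        parts.append("FLOW")
    if bn != "none":
        parts.append(f"BN_{bn.upper()}")
    return "_".join(parts)


def catalogue(priors: dict[str, Prior] | None = None) -> list[ScenarioSpec]:
    """The fixed 15-model catalogue: 6 split + 9 vicariance scenarios.

    Split: each origin (SEA, NEA) with {no flow; bidirectional flow;
    bidirectional flow + post-divergence bottlenecks in both regions}.
    The flow+bottleneck pair are the headline models (region-of-origin
    expansion with later shrinkage in both regions and asymmetric gene
    flow).  Vicariance: {no flow, bidirectional flow} crossed with
    bottleneck placement {none, SEA, NEA, both}, plus an equal-size
    no-bottleneck variant.
    """
    specs: list[ScenarioSpec] = []
    for origin in ("SEA", "NEA"):
        specs.append(build_split_scenario(origin, "none", "none", priors))
        specs.append(build_split_scenario(origin, "bidirectional", "none", priors))
        specs.append(build_split_scenario(origin, "bidirectional", "both", priors))
    for flow in ("none", "bidirectional"):
        for bn in ("none", "SEA", "NEA", "both"):
            specs.append(build_vicariance_scenario(flow, bn, False, priors))
    specs.append(build_vicariance_scenario("none", "none", True, priors))
    ids = [s.scenario_id for s in specs]
    assert len(set(ids)) == 15
    return specs


def compile_program(spec: ScenarioSpec, params: dict[str, float]) -> DemographyProgram:
    """Compile a concrete parameter draw into a backward-time demography."""
    n_ref, g = spec.n_ref, spec.generation_time
    tau = lambda ka: ka_to_coalescent_time(ka, n_ref, g)
    n_sea = params["N_SEA"]
    n_nea = params["N_SEA"] if spec.equal_sizes else params["N_NEA"]
    sizes = np.array([n_sea / n_ref, n_nea / n_ref])
    mig = np.zeros((2, 2))
    if spec.gene_flow == "bidirectional":
        # scaled backward rates 4*N*m = 4*Nm
        mig[0, 1] = 4.0 * params["Nm_SEA_NEA"]
        mig[1, 0] = 4.0 * params["Nm_NEA_SEA"]
    events: list[DemographicEvent] = []
    t_div = tau(params["T"])
    size_at_div = {"SEA": n_sea, "NEA": n_nea}

    if spec.family == "split":
        origin = spec.origin_pop
        derived = "NEA" if origin == "SEA" else "SEA"
        bn = spec._bottleneck_pops()
        # origin's size at divergence sets N_anc ("minimal or no change")
        if origin in bn:
            size_at_div[origin] = params[f"N_{origin}_b"]
            events.append(DemographicEvent(tau(params[f"T_{origin}"]), "size_change",
                                           source=POP_INDEX[origin],
                                           size=params[f"N_{origin}_b"] / n_ref))
        n_anc = size_at_div[origin]
        if derived in bn:
            # founding phase: derived at f*N_anc between its bottleneck time and T
            events.append(DemographicEvent(tau(params[f"T_{derived}"]), "size_change",
                                           source=POP_INDEX[derived],
                                           size=params["f"] * n_anc / n_ref))
        events.append(DemographicEvent(t_div, "merge",
                                       source=POP_INDEX[derived], dest=POP_INDEX[origin]))
        events.append(DemographicEvent(t_div, "size_change",
                                       source=POP_INDEX[origin], size=n_anc / n_ref))
    else:
        for region in spec._bottleneck_pops():
            size_at_div[region] = params[f"N_{region}_b"]
            events.append(DemographicEvent(tau(params[f"T_{region}"]), "size_change",
                                           source=POP_INDEX[region],
                                           size=params[f"N_{region}_b"] / n_ref))
        n_anc = size_at_div["SEA"] + size_at_div["NEA"]
        events.append(DemographicEvent(t_div, "merge", source=1, dest=0))
        events.append(DemographicEvent(t_div, "size_change", source=0, size=n_anc / n_ref))

    events.sort(key=lambda e: e.time)
    return DemographyProgram(2, sizes, mig, events, n_ref=n_ref)


def sample_prior(spec: ScenarioSpec, rng: np.random.Generator,
                 max_rejects: int = 10_000) -> ScenarioDraw:
    """Independent prior draws with T_region < T enforced by rejection."""
    for k, p in spec.priors.items():
        if p.dist != "point" and p.low >= p.high:
            raise ValueError(f"prior for {k}: lower >= upper")
    params = {k: p.sample(rng) for k, p in spec.priors.items()}
    time_params = [k for k in params if k.startswith("T_")]
    for k in time_params:
        tries = 0
        while params[k] >= params["T"]:
            params[k] = spec.priors[k].sample(rng)
            tries += 1
            if tries > max_rejects:
                raise RuntimeError(f"could not satisfy {k} < T by rejection")
    if spec.equal_sizes:
        params["N_NEA"] = params["N_SEA"]
    return ScenarioDraw(spec.scenario_id, params, compile_program(spec, params))


def ancestral_size(spec: ScenarioSpec, params: dict[str, float]) -> float:
    """N_anc implied by a draw (audit helper for the family invariants)."""
    size_at_div = {"SEA": params["N_SEA"],
                   "NEA": params["N_SEA"] if spec.equal_sizes else params["N_NEA"]}
    for region in spec._bottleneck_pops():
        key = f"N_{region}_b"
        if key in params:
            size_at_div[region] = params[key]
    if spec.family == "split":
        return size_at_div[spec.origin_pop]
    return size_at_div["SEA"] + size_at_div["NEA"]


def catalogue_to_json(specs: list[ScenarioSpec] | None = None, path=None) -> str:
    specs = specs if specs is not None else catalogue()
    text = json.dumps([s.to_config() for s in specs], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
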