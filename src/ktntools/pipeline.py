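"""End-to-end landscape exploration driver.

Mirrors, at synthetic scale, the standard discrete-path-sampling
protocol: seed several basin-hopping searches from distinct starting
structures, keep the lowest minima of each, merge them into one
database, connect the database into a single component, refine it
(SHORTCUT / UNTRAP / CONNECTUNC rounds), then analyse: harmonic
thermodynamics at 310 K, order parameters, potential- and free-energy
disconnectivity graphs, and the fastest path between the lowest-energy
helix-like and strand-like minima.  A comparison step tabulates the
helix/strand free-energy gap and path properties across protonation
presets.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import numpy as np
import yaml

from . import disconnectivity, thermo
from .basinhopping import basin_hopping, lowest_k
from .errors import NotConnectedError
from .ktn import (KTN, connectunc_refine, fastest_path,
                  integrated_path_length, shortcut_refine, untrap_refine,
                  write_ktn)
from .metrics import secondary_structure_fractions
from .models import (LJCluster, make_bead_peptide, make_lj_cluster,
                     make_muller_brown)
from .units import KB_KCAL, T_BODY

__all__ = ["RunConfig", "EnsembleSummary", "run_landscape",
           "run_preset_comparison", "compare_presets"]


@dataclass
class RunConfig:
    """Configuration of one landscape exploration run.

    Production-scale defaults follow the standard protocol (60,000
    basin-hopping steps per start, lowest 200 minima seeding); use
    :meth:`scaled` for a desk-scale profile.
    """

    system: str = "peptide"          # peptide | muller_brown | lj
    n_residues: int = 10
    preset: str = "prot1"
    ionic_strength: float = 0.1
    n_atoms: int = 7                 # for system == "lj"

    bh_steps: int = 60_000
    n_starts: int = 4
    bh_temperature: float = 1.0
    keep_lowest: int = 200
    seed: int = 0

    connect_cycles: int = 5
    connect_attempts: int = 60
    refine_rounds: int = 1
    shortcut_attempts: int = 3
    untrap_candidates: int = 2

    temperature: float = T_BODY
    kB: float = KB_KCAL
    regroup_threshold: float | None = None   # default 1 kT at `temperature`
    delta_e: float | None = None
    outdir: str | None = None

    @classmethod
    def scaled(cls, **overrides) -> "RunConfig":
        """Desk-scale profile: 2,000 steps, lowest-20, two starts."""
        base = dict(bh_steps=2000, keep_lowest=20, n_starts=2)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        positive = ["n_residues", "bh_steps", "n_starts", "keep_lowest",
                    "temperature"]
        for name in positive:
            if getattr(self, name) <= 0 and not (name == "bh_steps"):
                raise ValueError(f"{name} must be positive")
        if self.system not in ("peptide", "muller_brown", "lj"):
            raise ValueError(f"unknown system {self.system!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(str(path), "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class FunnelRow:
    funnel_id: int
    label: str
    free_energy: float
    occupation_probability: float
    mean_helix: float
    mean_strand: float
    mean_rg: float
    n_minima: int


@dataclass
class EnsembleSummary:
    """Headline numbers of one explored landscape."""

    preset: str
    temperature: float
    n_minima: int
    n_ts: int
    connected: bool
    funnels: list[FunnelRow]
    global_min_is_helix: bool | None
    helix_free_energy: float | None
    strand_free_energy: float | None
    delta_f_strand_minus_helix: float | None
    path_cost: float | None
    path_steps: int | None
    integrated_length: float | None
    settings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def _build_model(config: RunConfig):
    if config.system == "peptide":
        return make_bead_peptide(config.n_residues, config.preset,
                                 config.ionic_strength)
    if config.system == "muller_brown":
        return make_muller_brown()
    return make_lj_cluster(config.n_atoms)


def _starting_points(model, config: RunConfig, rng) -> list[np.ndarray]:
    starts = []
    if config.system == "peptide":
        starts.append(model.helix_configuration())
        starts.append(model.strand_configuration())
        while len(starts) < config.n_starts:
            dih = rng.uniform(0.0, 360.0, size=model.n_residues - 3)
            starts.append(model.build_chain(dih))
    elif config.system == "muller_brown":
        while len(starts) < config.n_starts:
            starts.append(rng.uniform([-1.5, -0.5], [1.2, 2.0]))
    else:
        while len(starts) < config.n_starts:
            starts.append(rng.normal(scale=1.0, size=model.dimension))
    return starts[: config.n_starts]


def _order_params(model, config: RunConfig, coords) -> dict[str, float]:
    if config.system != "peptide":
        return {}
    ops = secondary_structure_fractions(model, coords)
    return {"rg": ops.rg, "helix": ops.helix_fraction,
            "strand": ops.strand_fraction, "coil": ops.coil_fraction}


def run_landscape(config: RunConfig):
    """Execute the full protocol; returns (KTN, EnsembleSummary).

    With ``config.outdir`` set, also writes the network file, summary
    JSON, disconnectivity SVGs and a stage log.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    model = _build_model(config)
    rng = np.random.default_rng(config.seed)
    log: list[str] = []
    t0 = time.time()

    def stage(msg):
        log.append(f"[{time.time() - t0:8.1f}s] {msg}")

    # --- seed: multi-start basin-hopping, keep the lowest of each -------
    net = KTN(permute_identical=isinstance(model, LJCluster))
    starts = _starting_points(model, config, rng)
    for i, start in enumerate(starts):
        mset = basin_hopping(model, start, config.bh_steps,
                             temperature=config.bh_temperature,
                             seed=config.seed * 1000 + i)
        kept = lowest_k(mset, config.keep_lowest)
        for m in kept:
            m.order_params = _order_params(model, config, m.coordinates)
            net.add_minimum(m)
        stage(f"basin-hopping start {i}: {len(mset)} minima, kept {len(kept)}")
    stage(f"merged database: {len(net)} minima")

    # --- connect into one component -------------------------------------
    if config.connect_cycles > 0:
        connectunc_refine(net, model, distance_tol=np.inf,
                          max_cycles=config.connect_cycles,
                          max_attempts=config.connect_attempts)
    for m in net.minima.values():
        if not m.order_params:
            m.order_params = _order_params(model, config, m.coordinates)
    stage(f"connection: {net.n_ts} transition states, "
          f"{len(net.connected_components())} component(s)")

    # --- refinement rounds ----------------------------------------------
    for _ in range(config.refine_rounds):
        if config.connect_cycles <= 0:
            break
        helix_id, strand_id = _endpoint_ids(net)
        if helix_id is not None and strand_id is not None:
            try:
                p = fastest_path(net, helix_id, strand_id,
                                 config.temperature, config.kB)
                shortcut_refine(net, model, p,
                                max_attempts=config.shortcut_attempts,
                                max_cycles=config.connect_cycles)
            except NotConnectedError:
                pass
        untrap_refine(net, model, temperature=config.temperature,
                      n_candidates=config.untrap_candidates,
                      max_cycles=config.connect_cycles)
        connectunc_refine(net, model, distance_tol=np.inf,
                          max_cycles=config.connect_cycles,
                          max_attempts=config.connect_attempts)
    for m in net.minima.values():
        if not m.order_params:
            m.order_params = _order_params(model, config, m.coordinates)
    net.validate()
    stage(f"refined: {len(net)} minima, {net.n_ts} ts")

    # --- analysis ---------------------------------------------------------
    summary = summarize(net, config)
    stage("analysis complete")

    if config.outdir is not None:
        out = FsPath(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_ktn(net, out / "landscape.ktn")
        (out / "summary.json").write_text(summary.to_json() + "\n")
        try:
            tree = disconnectivity.build_tree(net, delta_e=config.delta_e)
            if config.system == "peptide":
                disconnectivity.color_tree(
                    tree, {i: m.order_params.get("helix", 0.0)
                           for i, m in net.minima.items()}, (0.0, 1.0))
            disconnectivity.render(tree, out / "pe_disconnectivity.svg")
            grouped = thermo.regroup_free_energy(
                net, config.temperature, _threshold(config), config.kB)
            ftree = disconnectivity.build_tree(grouped)
            disconnectivity.render(ftree, out / "fe_disconnectivity.svg")
        except ValueError as exc:
            stage(f"disconnectivity rendering skipped: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        config.to_yaml(out / "config.yaml")
    return net, summary


def _threshold(config: RunConfig) -> float:
    if config.regroup_threshold is not None:
        return config.regroup_threshold
    return config.kB * config.temperature


def _endpoint_ids(net: KTN) -> tuple[int | None, int | None]:
    """Lowest-energy minima with helix fraction >= 0.5 / strand >= 0.5."""
    helix_id = strand_id = None
    for mid in sorted(net.minima, key=lambda i: (net.minima[i].energy, i)):
        ops = net.minima[mid].order_params
        if helix_id is None and ops.get("helix", 0.0) >= 0.5:
            helix_id = mid
        if strand_id is None and ops.get("strand", 0.0) >= 0.5:
            strand_id = mid
    return helix_id, strand_id


def summarize(net: KTN, config: RunConfig) -> EnsembleSummary:
    """Thermodynamic / structural summary of an explored network."""
    kB, T = config.kB, config.temperature
    kT = kB * T
    probs = thermo.occupation_probabilities(net, T, kB)
    grouped = thermo.regroup_free_energy(net, T, _threshold(config), kB)
    funnels = []
    for gi, g in enumerate(grouped.groups):
        mids = sorted(g.member_min_ids)
        w = np.array([probs[i] for i in mids])
        w = w / w.sum() if w.sum() > 0 else np.full(len(mids), 1 / len(mids))
        def wavg(key):
            return float(sum(wi * net.minima[i].order_params.get(key, 0.0)
                             for wi, i in zip(w, mids)))
        mh, ms, mrg = wavg("helix"), wavg("strand"), wavg("rg")
        label = "helix" if mh > ms else ("strand" if ms > mh else "coil")
        funnels.append(FunnelRow(funnel_id=gi, label=label,
                                 free_energy=g.free_energy,
                                 occupation_probability=g.occupation_probability,
                                 mean_helix=mh, mean_strand=ms, mean_rg=mrg,
                                 n_minima=len(mids)))
    # ensemble-level helix/strand free energies over all minima
    def ensemble_f(key):
        lnz = [thermo.ln_z_harmonic(m, T, kB)
               for m in net.minima.values()
               if m.order_params.get(key, 0.0) >= 0.5]
        if not lnz:
            return None
        from scipy.special import logsumexp
        return float(-kT * logsumexp(lnz))

    f_h = ensemble_f("helix")
    f_s = ensemble_f("strand")
    delta = (f_s - f_h) if (f_h is not None and f_s is not None) else None
    gmin = max(probs, key=lambda i: (probs[i], -i))
    gm_helix = None
    if config.system == "peptide":
        gm_helix = net.minima[gmin].order_params.get("helix", 0.0) >= 0.5
    # fastest helix <-> strand path
    path_cost = path_steps = int_len = None
    helix_id, strand_id = _endpoint_ids(net)
    if helix_id is not None and strand_id is not None:
        try:
            p = fastest_path(net, helix_id, strand_id, T, kB)
            path_cost = p.cost
            path_steps = len(p)
            int_len = integrated_path_length(net, p)
        except NotConnectedError:
            pass
    return EnsembleSummary(
        preset=config.preset if config.system == "peptide" else config.system,
        temperature=T, n_minima=len(net), n_ts=net.n_ts,
        connected=net.is_connected(), funnels=funnels,
        global_min_is_helix=gm_helix,
        helix_free_energy=f_h, strand_free_energy=f_s,
        delta_f_strand_minus_helix=delta,
        path_cost=path_cost, path_steps=path_steps,
        integrated_length=int_len,
        settings=dict(temperature=T, kB=kB,
                      regroup_threshold=_threshold(config),
                      system=config.system))


def run_preset_comparison(presets=("prot1", "prot2", "prot3"),
                          seed: int = 0, outdir: str | None = None,
                          **config_overrides):
    """Run the landscape protocol for several charge presets and
    cross-seed their databases.

    After the per-preset explorations, every minimum found under one
    preset is re-minimised under each of the others and merged into that
    preset's database (low-energy structures from one system seed the
    others), so the free-energy comparison is taken over a common
    structural library rather than whatever each search happened to
    find.  Returns (networks, summaries) keyed by preset name.
    """
    nets: dict[str, KTN] = {}
    cfgs: dict[str, RunConfig] = {}
    for preset in presets:
        cfg = RunConfig.scaled(preset=preset, seed=seed,
                               **config_overrides)
        if outdir is not None:
            cfg.outdir = f"{outdir}/{preset}"
        nets[preset], _ = run_landscape(cfg)
        cfgs[preset] = cfg
    # cross-seed: re-minimise every foreign minimum under each preset
    from .localopt import minimize as _minimize

    coords_by_preset = {p: [m.coordinates for m in nets[p].minima.values()]
                        for p in presets}
    summaries: dict[str, EnsembleSummary] = {}
    for preset in presets:
        model = _build_model(cfgs[preset])
        net = nets[preset]
        for other in presets:
            if other == preset:
                continue
            for x in coords_by_preset[other]:
                try:
                    m = _minimize(model, x)
                except Exception:
                    continue
                m.order_params = _order_params(model, cfgs[preset], m.coordinates)
                net.add_minimum(m)
        connectunc_refine(net, model, distance_tol=np.inf,
                          max_cycles=cfgs[preset].connect_cycles,
                          max_attempts=cfgs[preset].connect_attempts // 2)
        for m in net.minima.values():
            if not m.order_params:
                m.order_params = _order_params(model, cfgs[preset],
                                               m.coordinates)
        summaries[preset] = summarize(net, cfgs[preset])
        if cfgs[preset].outdir is not None:
            out = FsPath(cfgs[preset].outdir)
            write_ktn(net, out / "landscape.ktn")
            (out / "summary.json").write_text(
                summaries[preset].to_json() + "\n")
    return nets, summaries


def compare_presets(summaries: dict[str, EnsembleSummary]) -> str:
    """Tab-separated comparison report across protonation presets.

    Requires >= 2 summaries computed with identical analysis settings;
    reports the strand-helix free-energy gap, funnel probabilities and
    fastest-path figures, plus ordering statements.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    settings = None
    for s in summaries.values():
        if settings is None:
            settings = s.settings
        elif s.settings != settings:
            raise ValueError("summaries have mismatched analysis settings")
    header = ["preset", "delta_f_strand_minus_helix", "helix_free_energy",
              "strand_free_energy", "global_min_is_helix", "path_cost",
              "integrated_length", "n_minima", "n_ts"]
    rows = [header]
    for name in sorted(summaries):
        s = summaries[name]

        def fmt(v):
            if v is None:
                return "NA"
            if isinstance(v, bool):
                return str(v).lower()
            if isinstance(v, float):
                return f"{v:.6f}"
            return str(v)
        rows.append([name, fmt(s.delta_f_strand_minus_helix),
                     fmt(s.helix_free_energy), fmt(s.strand_free_energy),
                     fmt(s.global_min_is_helix), fmt(s.path_cost),
                     fmt(s.integrated_length), str(s.n_minima), str(s.n_ts)])
    lines = ["\t".join(r) for r in rows]
    gaps = {n: s.delta_f_strand_minus_helix for n, s in summaries.items()
            if s.delta_f_strand_minus_helix is not None}
    if gaps:
        largest = max(sorted(gaps), key=lambda n: gaps[n])
        smallest = min(sorted(gaps), key=lambda n: gaps[n])
        lines.append(f"# largest strand-helix gap: {largest}")
        lines.append(f"# smallest strand-helix gap: {smallest}")
    lengths = {n: s.integrated_length for n, s in summaries.items()
               if s.integrated_length is not None}
    if lengths:
        shortest = min(sorted(lengths), key=lambda n: lengths[n])
        lines.append(f"# shortest integrated path: {shortest}")
    return "\n".join(lines) + "\n"
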