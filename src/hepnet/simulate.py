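"""Synthetic two-system expression compendia with planted regulatory networks.

The generator emulates the data shapes this pipeline consumes:

* a dose-series design (5 doses x 2 time points x 4 replicates, in-vivo
  style),
* a control-vs-treated design with 3 replicates (in-vitro style),
* large heterogeneous multi-condition compendia for network inference,

all driven by a pair of planted TF-module truth networks that share a
configurable conserved core.

Model. Each TF has a latent activity per sample: a dose-response term
(shared by all samples of a condition) plus Gaussian sample-level
variation — drawn per condition in compendia (array-to-array heterogeneity
across pseudo-compounds) and per replicate in designed studies (animal- or
culture-level variation). A target's log2 expression is its baseline plus
the signed slope times its regulator's activity plus measurement noise;
the TF's own expression tracks its activity; unconnected genes are pure
noise around their baselines. Values are emitted on the intensity scale
(2**log2) so the full normalization chain applies, with present/absent
flags derived from intensity.

Default scales: hub regulators swing ~6 log2 units at the top dose (the
many-ten-fold inductions typical of xenobiotic master responders), targets
transmit a damped fraction of that (slopes 0.20-0.26 per unit activity,
i.e. ~2.3-3-fold target responses), replicate noise is 0.3 log2 units, and
compendia span a few hundred arrays as network-inference compendia do.
The damped slopes put the regulator-target correlation near 0.55-0.6 while
the indirect co-target correlation — close to its square — stays materially
weaker, which is the regime where background-standardized MI scoring is
informative rather than saturated.

All randomness descends from one seed through per-(stream, system, gene)
substreams, so enlarging the gene panel does not perturb existing genes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, StudyDesign, write_expression_matrix, write_study_design

__all__ = [
    "SimulationConfig",
    "TruthNetwork",
    "generate_truth_networks",
    "simulate_expression",
    "write_fixture_bundle",
    "planted_de_genes",
]

# substream identifiers
_TRUTH, _BASELINE, _ACTIVITY, _NOISE = 0, 1, 2, 3
_SYSTEMS = {"a": 0, "b": 1}
_DESIGNS = {"dose_series": 0, "control_treated": 1, "compendium": 2}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition settings for the paired-system simulator.

    Counts mirror the designs the pipeline targets: 5 doses (0 control,
    4.8-192 mg/kg) x 2 time points x 4 replicates for the dose series, a
    3-replicate control/treated pair, and a >=100-condition compendium per
    system for network inference. Noise and effect scales are in log2
    units.
    """

    n_genes: int = 200
    n_tfs: int = 10
    targets_per_tf: int = 8
    shared_module_count: int = 4
    doses: tuple = (0.0, 4.8, 48.0, 96.0, 192.0)
    time_points: tuple = (24.0, 48.0)
    replicates: int = 4
    vitro_replicates: int = 3
    vitro_dose: float = 10.0
    n_compendium_conditions: int = 240
    noise_sd: float = 0.3
    effect_sd: float = 1.0
    replicate_activity_sd: float = 0.3
    dose_amplitude: float = 6.0
    slope_range: tuple = (0.20, 0.26)
    dose_response: str = "linear_in_log_dose"
    baseline_mean: float = 9.0
    baseline_sd: float = 2.5
    flag_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_module_count > self.n_tfs:
            raise ValueError("shared_module_count cannot exceed n_tfs")
        if self.n_tfs + self.n_tfs * self.targets_per_tf > self.n_genes:
            raise ValueError(
                "n_genes too small for n_tfs TFs with targets_per_tf targets each"
            )
        if min(self.n_genes, self.n_tfs, self.targets_per_tf, self.replicates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dose_response not in ("linear_in_log_dose", "hill"):
            raise ValueError("dose_response must be linear_in_log_dose or hill")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @property
    def gene_ids(self) -> list[str]:
        others = [f"G{i + 1:04d}" for i in range(self.n_genes - self.n_tfs)]
        return self.tf_ids + others


@dataclass
class TruthNetwork:
    """Planted signed regulator->target edges with module provenance.

    ``edges`` columns: regulator, target, sign (+1/-1), effect (signed slope
    on the log2 scale), module (``shared`` or ``specific``).
    ``dose_signs`` maps each regulator to the sign of its dose response.
    """

    edges: pd.DataFrame
    regulators: list[str]
    dose_signs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.edges
        if (e["regulator"] == e["target"]).any():
            raise ValueError("self-edge in truth network")
        if e.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate edge in truth network")
        for tf in self.regulators:
            if (e["regulator"] == tf).sum() < 1:
                raise ValueError(f"regulator {tf} has no targets")

    def edge_set(self) -> set[frozenset]:
        return {
            frozenset((r, t))
            for r, t in zip(self.edges["regulator"], self.edges["target"])
        }

    def shared_edge_set(self) -> set[frozenset]:
        e = self.edges[self.edges["module"] == "shared"]
        return {frozenset((r, t)) for r, t in zip(e["regulator"], e["target"])}

    def targets_of(self, tf: str) -> list[str]:
        return list(self.edges.loc[self.edges["regulator"] == tf, "target"])


def generate_truth_networks(cfg: SimulationConfig) -> tuple[TruthNetwork, TruthNetwork]:
    """Draw the paired truth networks.

    The first ``shared_module_count`` TF modules are edge-identical across
    the two systems (same targets, same signs, same dose-response sign);
    remaining modules get independently drawn target sets and signs per
    system. Slope magnitudes are drawn per system for every edge, so the
    conserved core shares topology and direction but not exact kinetics.
    """
    tfs = cfg.tf_ids
    pool = [g for g in cfg.gene_ids if g not in tfs]
    rng_shared = _rng(cfg.seed, _TRUTH, 0)
    perm = rng_shared.permutation(len(pool))

    shared_rows = []
    used = 0
    for ti in range(cfg.shared_module_count):
        targets = [pool[j] for j in perm[used : used + cfg.targets_per_tf]]
        used += cfg.targets_per_tf
        signs = rng_shared.choice([-1, 1], size=cfg.targets_per_tf)
        shared_rows.append((tfs[ti], targets, signs))
    shared_dose_signs = {
        tfs[ti]: int(rng_shared.choice([-1, 1])) for ti in range(cfg.shared_module_count)
    }

    nets = []
    taken: dict[str, set[str]] = {}  # system a's specific targets per TF
    for sys_name, sys_id in _SYSTEMS.items():
        rng_sys = _rng(cfg.seed, _TRUTH, 1, sys_id)
        remaining = [pool[j] for j in perm[used:]]
        rows = []
        dose_signs = dict(shared_dose_signs)
        for tf, targets, signs in shared_rows:
            for t, s in zip(targets, signs):
                rows.append((tf, t, int(s), "shared"))
        sys_perm = list(rng_sys.permutation(len(remaining)))
        for ti in range(cfg.shared_module_count, cfg.n_tfs):
            tf = tfs[ti]
            # the second system may reuse another TF's targets (cross-system
            # target overlap is realistic) but never replicate the exact
            # regulator->target pair of the first system
            forbidden = taken.get(tf, set()) if sys_name == "b" else set()
            targets: list[str] = []
            chosen: set[int] = set()
            for j in sys_perm:
                if len(targets) == cfg.targets_per_tf:
                    break
                if remaining[j] in forbidden:
                    continue
                targets.append(remaining[j])
                chosen.add(j)
            sys_perm = [j for j in sys_perm if j not in chosen]
            if sys_name == "a":
                taken[tf] = set(targets)
            signs = rng_sys.choice([-1, 1], size=cfg.targets_per_tf)
            for t, s in zip(targets, signs):
                rows.append((tf, t, int(s), "specific"))
            dose_signs[tf] = int(rng_sys.choice([-1, 1]))
        lo, hi = cfg.slope_range
        mags = rng_sys.uniform(lo, hi, size=len(rows))
        edges = pd.DataFrame(
            rows, columns=["regulator", "target", "sign", "module"]
        )
        edges["effect"] = edges["sign"] * mags
        nets.append(
            TruthNetwork(
                edges[["regulator", "target", "sign", "effect", "module"]],
                regulators=list(tfs),
                dose_signs=dose_signs,
            )
        )
    return nets[0], nets[1]


def _dose_curve(doses: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Normalized dose-response f(d) in [0, 1], f(0)=0, f(max)=1."""
    doses = np.asarray(doses, dtype=float)
    positive = doses[doses > 0]
    if positive.size == 0:
        return np.zeros_like(doses)
    if cfg.dose_response == "linear_in_log_dose":
        d_ref = positive.min()
        f = np.log2(1.0 + doses / d_ref)
        return f / np.log2(1.0 + doses.max() / d_ref)
    # hill with K at the median positive dose, coefficient 2
    K = float(np.median(positive))
    f = doses**2 / (doses**2 + K**2)
    return f / (doses.max() ** 2 / (doses.max() ** 2 + K**2))


def _design_table(cfg: SimulationConfig, design: str, system: str) -> pd.DataFrame:
    rows = []
    if design == "dose_series":
        for t in cfg.time_points:
            for d in cfg.doses:
                for r in range(1, cfg.replicates + 1):
                    rows.append(
                        (
                            f"{system}_d{d:g}_t{t:g}_r{r}",
                            system,
                            "TNT",
                            d,
                            t,
                            r,
                            d == 0,
                        )
                    )
    elif design == "control_treated":
        for d, tag in ((0.0, "ctrl"), (cfg.vitro_dose, "trt")):
            for r in range(1, cfg.vitro_replicates + 1):
                rows.append(
                    (f"{system}_{tag}_r{r}", system, "TNT", d, 24.0, r, d == 0)
                )
    elif design == "compendium":
        for c in range(1, cfg.n_compendium_conditions + 1):
            rows.append(
                (f"{system}_cmp{c:03d}", system, f"C{c:03d}", 0.0, 24.0, 1, False)
            )
    else:
        raise ValueError(f"unknown design {design!r}")
    return pd.DataFrame(
        rows,
        columns=["sample_id", "system", "compound", "dose", "time_h", "replicate", "is_control"],
    )


def simulate_expression(
    truth: TruthNetwork,
    cfg: SimulationConfig,
    design: str = "dose_series",
    system: str = "a",
) -> tuple[ExpressionMatrix, StudyDesign]:
    """Simulate one expression matrix (intensity scale) plus its design table."""
    sys_id = _SYSTEMS[system]
    design_id = _DESIGNS[design]
    table = _design_table(cfg, design, system)
    n = len(table)
    genes = cfg.gene_ids
    gpos = {g: i for i, g in enumerate(genes)}

    # TF activities per sample
    activity = np.zeros((cfg.n_tfs, n))
    dose_f = _dose_curve(table["dose"].to_numpy(), cfg)
    for ti, tf in enumerate(cfg.tf_ids):
        rng = _rng(cfg.seed, _ACTIVITY, sys_id, design_id, ti)
        sign = truth.dose_signs.get(tf, 1)
        if design == "compendium":
            activity[ti] = rng.normal(0.0, cfg.effect_sd, size=n)
        else:
            activity[ti] = sign * cfg.dose_amplitude * dose_f + rng.normal(
                0.0, cfg.replicate_activity_sd, size=n
            )

    log2 = np.zeros((len(genes), n))
    for gi, g in enumerate(genes):
        base = float(
            _rng(cfg.seed, _BASELINE, sys_id, gi).normal(
                cfg.baseline_mean, cfg.baseline_sd
            )
        )
        noise = _rng(cfg.seed, _NOISE, sys_id, design_id, gi).normal(
            0.0, cfg.noise_sd, size=n
        )
        log2[gi] = base + noise
    for ti, tf in enumerate(cfg.tf_ids):
        log2[gpos[tf]] += activity[ti]
    for _, row in truth.edges.iterrows():
        ti = gpos[row["regulator"]]
        log2[gpos[row["target"]]] += row["effect"] * activity[ti]

    intensities = np.exp2(log2)
    values = pd.DataFrame(intensities, index=genes, columns=table["sample_id"])
    flags = pd.DataFrame(
        intensities >= cfg.flag_threshold, index=genes, columns=table["sample_id"]
    )
    return ExpressionMatrix(values, "intensity", flags), StudyDesign(table)


def planted_de_genes(
    truth: TruthNetwork, cfg: SimulationConfig, min_log2_shift: float = 1.0
) -> set[str]:
    """Genes whose expected top-dose log2 shift is at least ``min_log2_shift``.

    TFs shift by the full dose amplitude; targets by |slope| times it.
    """
    out = {
        tf for tf in truth.regulators if cfg.dose_amplitude >= min_log2_shift
    }
    shift = truth.edges["effect"].abs() * cfg.dose_amplitude
    out |= set(truth.edges.loc[shift >= min_log2_shift, "target"])
    return out


def write_fixture_bundle(cfg: SimulationConfig, out_dir) -> dict:
    """Write every pipeline input for both systems; returns a path manifest.

    Files: per system a dose-series or control/treated matrix + flags +
    design, a compendium matrix + design, a truth edge list; plus the shared
    TF list. Deterministic given the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_a, truth_b = generate_truth_networks(cfg)
    paths: dict[str, str] = {}

    jobs = [
        ("a", truth_a, "dose_series", "vivo"),
        ("a", truth_a, "compendium", "vivo_compendium"),
        ("b", truth_b, "control_treated", "vitro"),
        ("b", truth_b, "compendium", "vitro_compendium"),
    ]
    for system, truth, design, stem in jobs:
        m, d = simulate_expression(truth, cfg, design=design, system=system)
        mp, fp, dp = (
            out / f"{stem}_matrix.tsv",
            out / f"{stem}_flags.tsv",
            out / f"{stem}_design.tsv",
        )
        write_expression_matrix(m, mp, fp)
        write_study_design(d, dp)
        paths[f"{stem}_matrix"] = str(mp)
        paths[f"{stem}_flags"] = str(fp)
        paths[f"{stem}_design"] = str(dp)
    for name, truth in (("a", truth_a), ("b", truth_b)):
        tp = out / f"truth_edges_{name}.tsv"
        truth.edges.to_csv(tp, sep="\t", index=False, float_format="%.6g")
        paths[f"truth_edges_{name}"] = str(tp)
    tf_path = out / "tf_list.txt"
    tf_path.write_text("\n".join(cfg.tf_ids) + "\n", encoding="utf-8")
    paths["tf_list"] = str(tf_path)
    return paths


def bundle_checksum(paths: dict) -> str:
    """SHA-256 over the concatenated bundle files (sorted by key)."""
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(key.encode())
        h.update(Path(paths[key]).read_bytes())
    return h.hexdigest()
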