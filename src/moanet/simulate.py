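"""Synthetic toxicogenomic study generator.

Emulates the statistical structure of a multi-chemical rat-liver expression
study: five modes of action (MOAs) with three chemicals each, triplicate
exposures, vehicle/route batch structure with matched vehicle controls,
per-gene MOA fixed effects on a subset of genes, and planted co-expression
modules driven by latent eigengene factors that are either shared between the
receptor-mediated (RM) and non-receptor-mediated (NRM) sample classes
(preserved) or independently redrawn for the NRM samples (non-preserved).

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import control_group_key

__all__ = [
    "StudyDesign",
    "ModuleSpec",
    "SyntheticTruth",
    "generate_study",
    "generate_class_pair",
    "generate_probe_level",
    "generate_null_study",
    "write_module_gmt",
]

#: MOA -> chemical class used throughout: receptors (AhR, CAR/PXR, PPARA)
#: are receptor-mediated, cytotoxicity and DNA damage are not.
DEFAULT_MOA_CLASS_MAP = {
    "AhR": "RM",
    "CAR/PXR": "RM",
    "PPARA": "RM",
    "Cytotox": "NRM",
    "DNA_damage": "NRM",
}

DEFAULT_CHEMICALS = {
    "AhR": ["3ME", "LEF", "NAP"],
    "CAR/PXR": ["PHE", "MET", "ECO"],
    "PPARA": ["PIR", "BEZ", "NAF"],
    "Cytotox": ["CHO", "THI", "CAR"],
    "DNA_damage": ["AFL", "IFO", "NIT"],
}

# (vehicle, route) combinations cycled over the chemicals within each MOA.
# They span the three control-matching groups (nutritional-oral,
# non-nutritional-injection, non-nutritional-oral) so that route batches are
# not confounded with MOA.
_VEHICLE_ROUTE_CYCLE = [
    ("corn_oil", "oral"),
    ("saline", "injection"),
    ("CMC", "oral"),
]


class ConfigurationError(ValueError):
    """Raised when a study or module specification is internally inconsistent."""


@dataclass
class StudyDesign:
    """Factorial layout of a synthetic multi-chemical study.

    Defaults reproduce the reference design: 5 MOAs x 3 chemicals x 3
    replicates (45 treated samples) with three matched control groups.
    """

    n_moas: int = 5
    chemicals_per_moa: int = 3
    replicates: int = 3
    moa_class_map: dict = field(default_factory=lambda: dict(DEFAULT_MOA_CLASS_MAP))
    chemicals: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_CHEMICALS.items()})
    controls_per_group: int = 3

    def __post_init__(self):
        moas = self.moas
        if len(moas) != self.n_moas:
            raise ConfigurationError(
                f"moa_class_map has {len(moas)} MOAs, expected n_moas={self.n_moas}"
            )
        for moa in moas:
            if self.moa_class_map[moa] not in ("RM", "NRM"):
                raise ConfigurationError(f"MOA {moa!r} has class {self.moa_class_map[moa]!r}")
        if set(self.chemicals) != set(moas):
            # auto-name chemicals for non-default designs
            self.chemicals = {
                moa: [f"{moa}_c{i + 1}" for i in range(self.chemicals_per_moa)] for moa in moas
            }
        for moa, chems in self.chemicals.items():
            if len(chems) != self.chemicals_per_moa:
                raise ConfigurationError(
                    f"MOA {moa!r} lists {len(chems)} chemicals, expected {self.chemicals_per_moa}"
                )
        all_chems = [c for chems in self.chemicals.values() for c in chems]
        if len(set(all_chems)) != len(all_chems):
            raise ConfigurationError("a chemical maps to more than one MOA")

    @property
    def moas(self) -> list:
        return list(self.moa_class_map)

    @property
    def n_treated(self) -> int:
        return self.n_moas * self.chemicals_per_moa * self.replicates

    def annotation(self) -> pd.DataFrame:
        """Sample annotation table for this design (treated rows then controls)."""
        rows = []
        for moa in self.moas:
            for ci, chem in enumerate(self.chemicals[moa]):
                vehicle, route = _VEHICLE_ROUTE_CYCLE[ci % len(_VEHICLE_ROUTE_CYCLE)]
                date = f"d{1 + len(rows) // self.replicates:03d}"
                for rep in range(1, self.replicates + 1):
                    rows.append(
                        dict(
                            sample_id=f"{chem}_r{rep}",
                            chemical=chem,
                            moa=moa,
                            cls=self.moa_class_map[moa],
                            vehicle=vehicle,
                            route=route,
                            date=date,
                            role="treated",
                            replicate=rep,
                        )
                    )
        seen = []
        for vehicle, route in _VEHICLE_ROUTE_CYCLE:
            key = control_group_key(vehicle, route)
            if key in seen:
                continue
            seen.append(key)
            for i in range(1, self.controls_per_group + 1):
                rows.append(
                    dict(
                        sample_id=f"CTL_{key}_{i}",
                        chemical="vehicle",
                        moa="control",
                        cls="control",
                        vehicle=vehicle,
                        route=route,
                        date=f"d{900 + i:03d}",
                        role="control",
                        replicate=i,
                    )
                )
        annot = pd.DataFrame(rows).rename(columns={"cls": "class"})
        return annot.set_index("sample_id", drop=False)


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``eigengene_loading_range`` bounds the per-gene loading on the module's
    latent factor. Loadings follow the kME convention: a gene with loading l
    is generated as ``l * F + sqrt(1 - l^2) * noise_sd * eps`` with F the
    unit-variance module eigengene factor, so at unit noise l equals the
    gene-eigengene correlation and two genes with loadings l1, l2 have
    expected correlation l1*l2 (more generally
    l1*l2 / sqrt((l1^2+(1-l1^2)sd^2)(l2^2+(1-l2^2)sd^2))).

    ``preserved_in_test`` controls whether the test (NRM) class keeps the
    module's co-expression structure. When False, ``break_mode`` selects how
    it is broken:

    * ``"decohere"`` (default): each module gene gets a private,
      variance-matched factor in the test class — both density and
      connectivity are destroyed there;
    * ``"rewire"``: the test class shares a freshly drawn factor but the
      gene loadings are randomly permuted (and sign-flipped per
      ``class_specific_sign_flip_fraction``) — the module stays co-expressed
      (density kept) while its gene-level connectivity pattern is destroyed.
    """

    module_id: str
    size: int
    eigengene_loading_range: tuple = (0.5, 0.9)
    preserved_in_test: bool = True
    break_mode: str = "decohere"
    class_specific_sign_flip_fraction: float = 0.0

    def __post_init__(self):
        lo, hi = self.eigengene_loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(
                f"loading range {self.eigengene_loading_range} not within (0, 1]"
            )
        if self.size < 2:
            raise ConfigurationError(f"module {self.module_id!r} smaller than 2 genes")
        if self.break_mode not in ("decohere", "rewire"):
            raise ConfigurationError(f"unknown break_mode {self.break_mode!r}")
        if not 0.0 <= self.class_specific_sign_flip_fraction <= 1.0:
            raise ConfigurationError("sign-flip fraction outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    seed: int
    module_of_gene: dict            # gene id -> module id (planted genes only)
    loadings: dict                  # gene id -> latent-factor loading
    moa_effects: dict               # gene id -> {moa: effect} for affected genes
    batch_offsets: dict             # route -> per-gene offset array (as list)
    preserved: dict                 # module id -> bool
    probe_map: dict = field(default_factory=dict)   # probe id -> probe-set id
    rogue_probe_sets: list = field(default_factory=list)

    def module_genes(self, module_id: str) -> list:
        return [g for g, m in self.module_of_gene.items() if m == module_id]

    @property
    def moa_affected_genes(self) -> set:
        return set(self.moa_effects)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "module_of_gene": self.module_of_gene,
                    "loadings": self.loadings,
                    "moa_effects": self.moa_effects,
                    "batch_offsets": {k: list(map(float, v)) for k, v in self.batch_offsets.items()},
                    "preserved": self.preserved,
                    "probe_map": self.probe_map,
                    "rogue_probe_sets": self.rogue_probe_sets,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _gene_ids(n_genes: int) -> list:
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def generate_study(
    design: StudyDesign,
    modules: list | None = None,
    n_genes: int = 2000,
    noise_sd: float = 1.0,
    seed: int = 0,
    moa_affected_fraction: float = 0.10,
    moa_effect_sd: float | None = None,
    batch_sd: float = 0.5,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    moa_factor_sd: float = 1.0,
    chem_factor_sd: float = 1.0,
    sample_factor_sd: float = 1.0,
):
    """Simulate a full study on the log2 scale.

    Treated sample expression is
    ``baseline + route offset + MOA effect + loading * latent + noise``;
    matched controls receive ``baseline + route offset + noise`` only.

    The latent module eigengene for treated sample ``s`` is

        f_s = (moa_factor_sd * m_{moa(s)} + chem_factor_sd * c_{chem(s)}
               + sample_factor_sd * e_s) / V

    with m, c, e i.i.d. standard normal and V normalizing f to unit variance:
    modules respond coherently to treatment (a per-MOA and a per-chemical
    component, as co-regulated pathways do) on top of per-sample biological
    variation. With both treatment scales set to 0 this reduces to the pure
    per-sample factor model. A module gene with loading l contributes
    ``l * f`` and receives residual noise ``sqrt(1 - l^2) * noise_sd`` (kME
    loading convention, see :class:`ModuleSpec`). Preserved modules use the
    same loadings in both classes; non-preserved modules are broken in the
    NRM treated samples according to their ``break_mode``.

    A ``moa_affected_fraction`` of background (non-module) genes additionally
    carry independent per-gene MOA effect vectors (sd ``moa_effect_sd``,
    default 3x noise); module genes are MOA-responsive through their factor,
    and their implied per-MOA effects are recorded in the truth.

    Returns ``(expression, annotation, truth)``.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    modules = list(modules or [])
    total_module = sum(m.size for m in modules)
    if total_module > n_genes:
        raise ConfigurationError(
            f"module sizes sum to {total_module} > n_genes={n_genes}"
        )
    if len({m.module_id for m in modules}) != len(modules):
        raise ConfigurationError("duplicate module ids")
    if moa_effect_sd is None:
        moa_effect_sd = 3.0 * noise_sd

    rng = np.random.default_rng(seed)
    annot = design.annotation()
    genes = _gene_ids(n_genes)
    samples = list(annot.index)
    treated_mask = (annot["role"] == "treated").to_numpy()
    n_samp = len(samples)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    routes = list(dict.fromkeys(annot["route"]))
    batch = {r: rng.normal(0.0, batch_sd, size=n_genes) for r in routes}

    X = np.tile(baseline[:, None], (1, n_samp))
    for r in routes:
        cols = (annot["route"] == r).to_numpy()
        X[:, cols] += batch[r][:, None]

    # assign module genes from a shuffled gene order, then MOA-affected genes
    order = rng.permutation(n_genes)
    module_of_gene: dict = {}
    loadings: dict = {}
    pos = 0
    module_rows: dict = {}
    for spec in modules:
        idx = order[pos : pos + spec.size]
        pos += spec.size
        module_rows[spec.module_id] = idx
        lo, hi = spec.eigengene_loading_range
        lam = rng.uniform(lo, hi, size=spec.size)
        for g_i, l in zip(idx, lam):
            module_of_gene[genes[g_i]] = spec.module_id
            loadings[genes[g_i]] = float(l)

    background = order[pos:]
    n_affected = int(round(moa_affected_fraction * n_genes))
    moa_levels = design.moas
    moa_effects: dict = {}
    for g_i in background[:n_affected]:
        eff = rng.normal(0.0, moa_effect_sd, size=len(moa_levels))
        moa_effects[genes[g_i]] = {m: float(e) for m, e in zip(moa_levels, eff)}
        for m, e in zip(moa_levels, eff):
            cols = treated_mask & (annot["moa"] == m).to_numpy()
            X[g_i, cols] += e

    # latent module factors on treated samples
    nrm_treated = treated_mask & (annot["class"] == "NRM").to_numpy()
    moa_of = annot["moa"].to_numpy()
    chem_of = annot["chemical"].to_numpy()
    factor_scale = float(np.sqrt(moa_factor_sd**2 + chem_factor_sd**2 + sample_factor_sd**2))
    if factor_scale == 0:
        raise ConfigurationError("at least one factor component must be positive")
    preserved: dict = {}

    # Distinct pathways respond to the 5 treatments in distinct ways: module
    # MOA response profiles are drawn zero-mean and mutually orthogonal
    # (spanning at most the n_moas - 1 dimensional centered contrast space)
    # so that planted modules stay identifiable at the design's MOA
    # resolution and per-route centering cannot re-couple them; chemical and
    # per-sample components stay independent. Profiles beyond the contrast
    # space fall back to independent centered draws.
    n_levels = len(moa_levels)
    n_ortho = min(len(modules), n_levels - 1) if n_levels > 1 else 0
    raw = rng.standard_normal((n_levels, max(n_ortho, 1)))
    raw -= raw.mean(axis=0, keepdims=True)
    Qm, _ = np.linalg.qr(raw)
    ortho_profiles = list((Qm[:, :n_ortho] * np.sqrt(n_levels)).T)
    profile_iter = iter(ortho_profiles)

    def _draw_factor():
        """Unit-variance latent factor over samples (0 on controls)."""
        prof = next(profile_iter, None)
        if prof is None:
            prof = rng.standard_normal(n_levels)
            prof -= prof.mean()
        m_eff = {m: float(v) for m, v in zip(moa_levels, prof)}
        c_eff = {c: rng.normal() for c in dict.fromkeys(chem_of[treated_mask])}
        f = np.zeros(n_samp)
        for s_i in np.where(treated_mask)[0]:
            f[s_i] = (
                moa_factor_sd * m_eff[moa_of[s_i]]
                + chem_factor_sd * c_eff[chem_of[s_i]]
                + sample_factor_sd * rng.normal()
            ) / factor_scale
        return f, m_eff

    noise_scale = np.full(n_genes, noise_sd)
    for spec in modules:
        idx = module_rows[spec.module_id]
        lam = np.array([loadings[genes[i]] for i in idx])
        noise_scale[idx] = noise_sd * np.sqrt(1.0 - lam**2)
        factor, m_eff = _draw_factor()
        preserved[spec.module_id] = bool(spec.preserved_in_test)
        contrib = lam[:, None] * factor[None, :]
        if not spec.preserved_in_test:
            nrm_cols = np.where(nrm_treated)[0]
            if spec.break_mode == "decohere":
                private = rng.standard_normal((spec.size, len(nrm_cols)))
                contrib[:, nrm_cols] = lam[:, None] * private
            else:  # rewire: shared redrawn factor, permuted/flipped loadings
                f2, _ = _draw_factor()
                lam2 = lam[rng.permutation(spec.size)]
                n_flip = int(round(spec.class_specific_sign_flip_fraction * spec.size))
                if n_flip:
                    flip = rng.choice(spec.size, size=n_flip, replace=False)
                    lam2 = lam2.copy()
                    lam2[flip] = -lam2[flip]
                contrib[:, nrm_cols] = lam2[:, None] * f2[nrm_cols][None, :]
        contrib[:, ~treated_mask] = 0.0
        X[idx, :] += contrib
        if moa_factor_sd > 0:
            # record the factor-implied MOA response of each module gene
            for g_i, l in zip(idx, lam):
                moa_effects[genes[g_i]] = {
                    m: float(l * moa_factor_sd * m_eff[m] / factor_scale)
                    for m in moa_levels
                }

    X += rng.standard_normal(X.shape) * noise_scale[:, None]

    expr = pd.DataFrame(X, index=genes, columns=samples)
    truth = SyntheticTruth(
        seed=seed,
        module_of_gene=module_of_gene,
        loadings=loadings,
        moa_effects=moa_effects,
        batch_offsets={r: batch[r].tolist() for r in routes},
        preserved=preserved,
    )
    return expr, annot, truth


def generate_null_study(design: StudyDesign, n_genes: int, seed: int, noise_sd: float = 1.0, batch_sd: float = 0.5):
    """Pure noise plus route batch offsets; no MOA effects, no modules."""
    expr, annot, _ = generate_study(
        design,
        modules=[],
        n_genes=n_genes,
        noise_sd=noise_sd,
        seed=seed,
        moa_affected_fraction=0.0,
        batch_sd=batch_sd,
    )
    return expr, annot


def generate_class_pair(
    modules: list,
    n_genes: int = 1000,
    n_samples_per_class: int = 15,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Two aligned expression matrices (reference and test class) with planted
    latent-factor modules; the minimal input for preservation statistics.

    Genes follow the pure per-sample factor model with the kME loading
    convention: a module gene with loading l is
    ``l * F + sqrt(1 - l^2) * noise_sd * eps`` (so at unit noise the expected
    within-module correlation is the loading product). Preserved modules keep
    the same loading structure in both classes (each class has its own factor
    realization); non-preserved modules lose all correlation structure in the
    test class (private, variance-matched factor per gene).

    Returns ``(ref_expr, test_expr, truth)`` with genes as rows.
    """
    modules = list(modules)
    total = sum(m.size for m in modules)
    if total > n_genes:
        raise ConfigurationError("module sizes exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    cols_ref = [f"REF_{i + 1:02d}" for i in range(n_samples_per_class)]
    cols_test = [f"TEST_{i + 1:02d}" for i in range(n_samples_per_class)]
    Xr = rng.normal(0.0, noise_sd, size=(n_genes, n_samples_per_class))
    Xt = rng.normal(0.0, noise_sd, size=(n_genes, n_samples_per_class))
    module_of_gene: dict = {}
    loadings: dict = {}
    preserved: dict = {}
    pos = 0
    for spec in modules:
        idx = np.arange(pos, pos + spec.size)
        pos += spec.size
        lo, hi = spec.eigengene_loading_range
        lam = rng.uniform(lo, hi, size=spec.size)
        shrink = np.sqrt(1.0 - lam**2)
        f_ref = rng.normal(size=n_samples_per_class)
        f_test = rng.normal(size=n_samples_per_class)
        Xr[idx, :] = lam[:, None] * f_ref[None, :] + shrink[:, None] * Xr[idx, :]
        if spec.preserved_in_test:
            Xt[idx, :] = lam[:, None] * f_test[None, :] + shrink[:, None] * Xt[idx, :]
        else:
            # destroy co-expression: private factor per gene keeps variance
            private = rng.normal(size=(spec.size, n_samples_per_class))
            Xt[idx, :] = lam[:, None] * private + shrink[:, None] * Xt[idx, :]
        preserved[spec.module_id] = bool(spec.preserved_in_test)
        for g_i, l in zip(idx, lam):
            module_of_gene[genes[g_i]] = spec.module_id
            loadings[genes[g_i]] = float(l)
    truth = SyntheticTruth(
        seed=seed,
        module_of_gene=module_of_gene,
        loadings=loadings,
        moa_effects={},
        batch_offsets={},
        preserved=preserved,
    )
    ref = pd.DataFrame(Xr, index=genes, columns=cols_ref)
    test = pd.DataFrame(Xt, index=genes, columns=cols_test)
    return ref, test, truth


def generate_probe_level(
    expr: pd.DataFrame,
    probes_per_set: int = 4,
    probe_noise_sd: float = 0.25,
    rogue_probe_fraction: float = 0.0,
    seed: int = 0,
):
    """Expand a probe-set level matrix into probes.

    Each probe is ``set signal + affinity constant + probe noise``. A
    ``rogue_probe_fraction`` of probe sets have their probes replaced by
    affinity plus independent noise whose variance matches signal-plus-noise,
    so they carry no consistent signal and should fail a consistency filter.

    Returns ``(probe_expr, probe_map)`` with ``probe_map`` a Series
    probe id -> probe-set id.
    """
    if probes_per_set < 2:
        raise ConfigurationError("probes_per_set must be >= 2")
    if not 0.0 <= rogue_probe_fraction <= 1.0:
        raise ConfigurationError("rogue_probe_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_sets, n_samp = expr.shape
    n_rogue = int(round(rogue_probe_fraction * n_sets))
    rogue_idx = set(rng.choice(n_sets, size=n_rogue, replace=False).tolist())

    rows = []
    probe_ids = []
    probe_map = {}
    rogue_sets = []
    sig = expr.to_numpy()
    for s_i, set_id in enumerate(expr.index):
        affin = rng.normal(0.0, 1.0, size=probes_per_set)
        signal = sig[s_i]
        sd_total = float(np.sqrt(signal.var(ddof=1) + probe_noise_sd**2)) or 1.0
        for p in range(probes_per_set):
            pid = f"{set_id}_p{p + 1}"
            if s_i in rogue_idx:
                vals = affin[p] + signal.mean() + rng.normal(0.0, sd_total, size=n_samp)
            else:
                vals = signal + affin[p] + rng.normal(0.0, probe_noise_sd, size=n_samp)
            rows.append(vals)
            probe_ids.append(pid)
            probe_map[pid] = set_id
        if s_i in rogue_idx:
            rogue_sets.append(set_id)
    probe_expr = pd.DataFrame(np.asarray(rows), index=probe_ids, columns=expr.columns)
    return probe_expr, pd.Series(probe_map, name="probe_set"), rogue_sets


def write_module_gmt(truth: SyntheticTruth, path, description: str = "planted module") -> None:
    """Write planted modules as GMT gene sets (one line per module)."""
    with open(path, "w") as fh:
        for mod in sorted(truth.preserved):
            genes = sorted(truth.module_genes(mod))
            fh.write("\t".join([mod, description] + genes) + "\n")
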