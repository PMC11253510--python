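"""Synthetic CyTOF-like references and patient cohorts with known truth.

The generator emulates the structure the analysis pipeline assumes, at desk
scale:

- **cell types** are isotropic Gaussian clusters in arcsinh space around
  per-type backbone profiles, drawn so that every pair of profiles has
  cosine similarity at most a separation cap (well-separated phenotypes);
- **samples** vary in cell-type composition via Dirichlet-distributed
  abundances;
- **signaling dependencies** are planted: for a chosen cell type and
  directed marker pair X -> Y, Y is overwritten with
  beta_group * X + Gaussian noise, with a different slope per outcome
  group — the ground-truth discriminative signal the survival models are
  supposed to recover;
- **survival** times are drawn consistently with the 60-month STS/LTS rule.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_model import ExpressionMatrix, ReferenceDataset, SurvivalTable
from .errors import ConfigError, DataError

__all__ = [
    "PlantedPair",
    "SyntheticSpec",
    "CohortData",
    "generate_reference",
    "generate_cohort",
    "truth_table",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_BACKBONE",
    "DEFAULT_SIGNALING",
]

DEFAULT_CELL_TYPES = (
    "B", "CD4_T", "CD8_T", "HSCs_MPPs", "Monocytes", "NK", "pDCs",
)
DEFAULT_BACKBONE = (
    "CD11b", "CD8a", "CD33", "CD34", "CD3", "CD123", "CD56", "CD14",
    "CD117", "CD38", "CD4", "CD16", "CD20", "CD45", "CD7",
)
DEFAULT_SIGNALING = (
    "pAxl", "CyclinB1", "pNFkB", "pErk", "pSTAT1", "pP38", "pSTAT3",
    "pCREB", "pHist3", "Casp3", "pSTAT5", "p4EBP1", "pAkt", "pRB", "pS6",
)


@dataclass(frozen=True)
class PlantedPair:
    """A directed dependency planted in one cell type, per outcome group."""

    cell_type: str
    x: str
    y: str
    beta_sts: float
    beta_lts: float
    noise_sd: float = 0.25


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic cohort.

    Defaults mirror the leukemia case study's shape: 7 detectable cell
    types over a 15-marker backbone and 15 signaling markers, and a cohort
    of 28 short-term plus 15 long-term survivors.
    """

    n_cell_types: int = 7
    backbone_dim: int = 15
    signaling_dim: int = 15
    cell_type_names: tuple[str, ...] = DEFAULT_CELL_TYPES
    backbone_names: tuple[str, ...] = DEFAULT_BACKBONE
    signaling_names: tuple[str, ...] = DEFAULT_SIGNALING
    separation_cap: float = 0.7
    within_type_sd: float = 0.2
    signaling_sd: float = 0.3
    n_samples_per_group: tuple[int, int] = (28, 15)  # (STS, LTS)
    cells_per_sample: int | tuple[int, int] = 3000
    cells_per_type_reference: int = 1000
    planted_pairs: tuple[PlantedPair, ...] = ()
    abundance_dirichlet: float | tuple[float, ...] = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2 or self.backbone_dim < 2 or self.signaling_dim < 2:
            raise ConfigError("need >= 2 cell types and >= 2 markers per panel")
        for name, dim in (
            ("cell_type_names", self.n_cell_types),
            ("backbone_names", self.backbone_dim),
            ("signaling_names", self.signaling_dim),
        ):
            names = tuple(getattr(self, name))
            if len(names) < dim:
                # extend the name pool with numbered names for larger panels
                extra = tuple(f"{name[:2].upper()}{i}" for i in range(len(names), dim))
                setattr(self, name, names + extra)
            else:
                setattr(self, name, names[:dim])
        if not 0 < self.separation_cap < 1:
            raise ConfigError("separation_cap must be in (0, 1)")
        for p in self.planted_pairs:
            if p.cell_type not in self.cell_type_names:
                raise ConfigError(f"planted pair cell type {p.cell_type!r} unknown")
            if p.x not in self.signaling_names or p.y not in self.signaling_names:
                raise ConfigError(
                    f"planted pair markers {p.x}->{p.y} must be signaling markers"
                )
            if not (np.isfinite(p.beta_sts) and np.isfinite(p.beta_lts)):
                raise ConfigError("planted betas must be finite")

    @property
    def marker_names(self) -> list[str]:
        return list(self.backbone_names) + list(self.signaling_names)


def _type_profiles(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Backbone profile per cell type, pairwise cosine <= separation_cap.

    Profiles are high/low marker signatures (high ~ U(2.5, 4.5) on ~35% of
    markers, low ~ U(0, 0.5) elsewhere) redrawn until the cap holds.
    """
    profiles: list[np.ndarray] = []
    for _ in range(spec.n_cell_types):
        for attempt in range(2000):
            high = rng.random(spec.backbone_dim) < 0.35
            if not high.any():
                continue
            prof = np.where(
                high,
                rng.uniform(2.5, 4.5, spec.backbone_dim),
                rng.uniform(0.0, 0.5, spec.backbone_dim),
            )
            ok = all(
                float(prof @ q / (np.linalg.norm(prof) * np.linalg.norm(q)))
                <= spec.separation_cap
                for q in profiles
            )
            if ok:
                profiles.append(prof)
                break
        else:
            raise DataError(
                f"could not place {spec.n_cell_types} profiles with pairwise "
                f"cosine <= {spec.separation_cap} in {spec.backbone_dim} dims"
            )
    return np.array(profiles)


def _signaling_profiles(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.5, 3.0, size=(spec.n_cell_types, spec.signaling_dim))


def _draw_cells(
    n: int,
    backbone_profile: np.ndarray,
    signaling_profile: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    bb = backbone_profile + rng.normal(0.0, spec.within_type_sd, (n, backbone_profile.size))
    sig = signaling_profile + rng.normal(0.0, spec.signaling_sd, (n, signaling_profile.size))
    return np.hstack([bb, sig])


def generate_reference(spec: SyntheticSpec) -> ReferenceDataset:
    """Labeled reference: ``cells_per_type_reference`` cells per type."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    backbone = _type_profiles(spec, rng)
    signaling = _signaling_profiles(spec, rng)
    blocks, labels = [], []
    for t, name in enumerate(spec.cell_type_names):
        blocks.append(
            _draw_cells(spec.cells_per_type_reference, backbone[t], signaling[t], spec, rng)
        )
        labels.extend([name] * spec.cells_per_type_reference)
    matrix = ExpressionMatrix(
        values=np.vstack(blocks),
        marker_names=spec.marker_names,
        cell_labels=np.array(labels, dtype=object),
        transformed=True,
    )
    return ReferenceDataset(matrix=matrix)


@dataclass
class CohortData:
    """A generated cohort: per-sample matrices, outcomes, and ground truth."""

    samples: dict[str, ExpressionMatrix]
    survival: SurvivalTable
    truth: dict

    def pooled_matrix(self) -> ExpressionMatrix:
        """All samples stacked, with sample ids and true labels attached."""
        mats = list(self.samples.values())
        return ExpressionMatrix(
            values=np.vstack([m.values for m in mats]),
            marker_names=mats[0].marker_names,
            cell_labels=np.concatenate([m.cell_labels for m in mats]),
            sample_ids=np.concatenate([m.sample_ids for m in mats]),
            transformed=True,
        )


def generate_cohort(spec: SyntheticSpec) -> CohortData:
    """Generate a patient cohort with planted group-specific dependencies."""
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    backbone = _type_profiles(spec, rng)  # same profiles as the reference
    signaling = _signaling_profiles(spec, rng)
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,))
    )

    alpha = spec.abundance_dirichlet
    if np.isscalar(alpha):
        alpha = np.full(spec.n_cell_types, float(alpha))
    else:
        alpha = np.asarray(alpha, dtype=float)
        if alpha.size != spec.n_cell_types:
            raise ConfigError("abundance_dirichlet length must equal n_cell_types")

    sig_index = {m: i for i, m in enumerate(spec.signaling_names)}
    n_sts, n_lts = spec.n_samples_per_group
    plan = [("STS", i + 1) for i in range(n_sts)] + [("LTS", i + 1) for i in range(n_lts)]

    samples: dict[str, ExpressionMatrix] = {}
    survival_rows = []
    truth_labels: dict[str, list[str]] = {}
    for group, number in plan:
        sample_id = f"{group}_{number:02d}"
        if isinstance(spec.cells_per_sample, tuple):
            lo, hi = spec.cells_per_sample
            n_cells = int(cohort_rng.integers(lo, hi + 1))
        else:
            n_cells = int(spec.cells_per_sample)
        props = cohort_rng.dirichlet(alpha)
        counts = cohort_rng.multinomial(n_cells, props)
        blocks, labels = [], []
        for t, name in enumerate(spec.cell_type_names):
            if counts[t] == 0:
                continue
            cells = _draw_cells(counts[t], backbone[t], signaling[t], spec, cohort_rng)
            for p in spec.planted_pairs:
                if p.cell_type != name:
                    continue
                beta = p.beta_sts if group == "STS" else p.beta_lts
                xi = spec.backbone_dim + sig_index[p.x]
                yi = spec.backbone_dim + sig_index[p.y]
                cells[:, yi] = beta * cells[:, xi] + cohort_rng.normal(
                    0.0, p.noise_sd, counts[t]
                )
            blocks.append(cells)
            labels.extend([name] * counts[t])
        samples[sample_id] = ExpressionMatrix(
            values=np.vstack(blocks),
            marker_names=spec.marker_names,
            cell_labels=np.array(labels, dtype=object),
            sample_ids=np.full(len(labels), sample_id, dtype=object),
            transformed=True,
        )
        truth_labels[sample_id] = labels
        months = (
            float(cohort_rng.uniform(2.0, 59.0))
            if group == "STS"
            else float(cohort_rng.uniform(60.0, 140.0))
        )
        survival_rows.append(
            {"sample_id": sample_id, "group": group, "survival_months": months}
        )

    truth = {
        "planted_pairs": [asdict(p) for p in spec.planted_pairs],
        "group_effects": {
            f"{p.cell_type}:{p.x}->{p.y}": {"beta_sts": p.beta_sts, "beta_lts": p.beta_lts}
            for p in spec.planted_pairs
        },
        "cell_labels": truth_labels,
        "groups": {r["sample_id"]: r["group"] for r in survival_rows},
        "seed": spec.seed,
    }
    return CohortData(
        samples=samples,
        survival=SurvivalTable(pd.DataFrame(survival_rows)),
        truth=truth,
    )


def truth_table(spec: SyntheticSpec) -> dict:
    """Machine-readable ground truth of the cohort this spec generates.

    Regenerates deterministically from the spec; round-trips through JSON.
    """
    truth = generate_cohort(spec).truth
    return json.loads(json.dumps(truth))


def write_cohort(cohort: CohortData, out_dir: str | Path) -> list[Path]:
    """Write reference-style CSVs, clinical table and truth JSON to a directory."""
    from .data_model import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for sample_id, m in cohort.samples.items():
        p = out / f"{sample_id}.csv"
        write_expression(m, p)
        written.append(p)
    clin = out / "clinical.csv"
    cohort.survival.table.to_csv(clin, index=False)
    written.append(clin)
    tj = out / "truth.json"
    tj.write_text(json.dumps(cohort.truth, indent=1))
    written.append(tj)
    return written
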