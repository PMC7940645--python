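"""Synthetic multi-group cohorts with block-structured connectivity.

The generator emulates the study design the pipeline targets: four
diagnostic groups (early AD n=16, MCI n=18, SCD n=16, healthy controls
n=23) of subjects measured on the ROIs of seven neurotransmitter pathway
networks.  Group differences are encoded purely through the strength of
within-pathway correlation — weaker coupling means the group's networks
integrate more slowly under filtration — while mean uptake is held equal
across groups.  Each group is drawn from a block-exchangeable
multivariate normal (unit variances; ``within`` inside a pathway block,
``between`` across blocks) plus i.i.d. Gaussian measurement noise, which
attenuates every correlation by ``1 / (1 + noise_sd**2)``.

Per-group random streams are derived from the master seed and the CRC32
of the group name, so adding or reordering groups never perturbs the
draws of the others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import ROI, PathwayDefinition, SubjectMatrix

__all__ = [
    "SyntheticSpec",
    "build_group_covariance",
    "generate_cohort",
    "write_cohort",
    "default_layout",
    "default_spec",
    "pathways_from_layout",
]

#: ROI counts mirroring the seven default pathway networks (bilateral
#: regions counted twice, midline once).
DEFAULT_LAYOUT: tuple[tuple[str, int], ...] = (
    ("striatocortical", 12),
    ("mesolimbic", 14),
    ("ch1_3", 8),
    ("ch4_medial", 6),
    ("ch4_lateral_perisylvian", 8),
    ("ch4_lateral_capsular", 10),
    ("ch5_6", 11),
)

#: Study-design defaults: group sizes from the emulated cohort, and a
#: within-pathway connectivity gradient HC > SCD > AD > MCI expressing
#: progressively attenuated metabolic coupling.
DEFAULT_GROUPS: tuple[tuple[str, int, float], ...] = (
    ("AD", 16, 0.45),
    ("MCI", 18, 0.35),
    ("SCD", 16, 0.60),
    ("HC", 23, 0.70),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort; reproducible given ``seed``."""

    group_names: tuple[str, ...]
    group_sizes: tuple[int, ...]
    pathway_layout: tuple[tuple[str, int], ...]
    within_strength: tuple[float, ...]
    between_strength: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.group_names)) != len(self.group_names):
            raise ValueError("group_names must be unique")
        if not (len(self.group_names) == len(self.group_sizes) == len(self.within_strength)):
            raise ValueError("group_names, group_sizes and within_strength must align")
        for name, n in zip(self.group_names, self.group_sizes):
            if n < 3:
                raise ValueError(
                    f"group {name!r}: size {n} < 3; Pearson correlation needs "
                    "at least 3 subjects"
                )
        for name, k in self.pathway_layout:
            if k < 1:
                raise ValueError(f"pathway {name!r}: ROI count must be positive")
        for name, w in zip(self.group_names, self.within_strength):
            if not 0.0 <= w < 1.0:
                raise ValueError(f"group {name!r}: within_strength {w} outside [0, 1)")
        if not 0.0 <= self.between_strength < 1.0:
            raise ValueError(f"between_strength {self.between_strength} outside [0, 1)")
        if self.within_strength and self.between_strength > min(self.within_strength):
            raise ValueError(
                f"between_strength {self.between_strength} must not exceed the "
                f"smallest within_strength {min(self.within_strength)}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd {self.noise_sd} must be nonnegative")

    @property
    def roi_names(self) -> list[str]:
        return [
            f"{pname}_{k + 1:02d}" for pname, count in self.pathway_layout for k in range(count)
        ]

    @property
    def n_rois(self) -> int:
        return sum(count for _, count in self.pathway_layout)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticSpec":
        return cls(
            group_names=tuple(doc["group_names"]),
            group_sizes=tuple(int(n) for n in doc["group_sizes"]),
            pathway_layout=tuple((str(p), int(k)) for p, k in doc["pathway_layout"]),
            within_strength=tuple(float(w) for w in doc["within_strength"]),
            between_strength=float(doc["between_strength"]),
            noise_sd=float(doc["noise_sd"]),
            seed=int(doc["seed"]),
        )


def default_layout() -> tuple[tuple[str, int], ...]:
    return DEFAULT_LAYOUT


def default_spec(seed: int = 0, noise_sd: float = 0.5, between_strength: float = 0.1) -> SyntheticSpec:
    """The study-design default: 4 groups, 7 pathway blocks, 69 ROIs."""
    names, sizes, within = zip(*DEFAULT_GROUPS)
    return SyntheticSpec(
        group_names=names,
        group_sizes=sizes,
        pathway_layout=DEFAULT_LAYOUT,
        within_strength=within,
        between_strength=between_strength,
        noise_sd=noise_sd,
        seed=seed,
    )


def pathways_from_layout(layout) -> list[PathwayDefinition]:
    """Pathway definitions whose ROI names match generated cohort columns."""
    out = []
    for pname, count in layout:
        rois = tuple(ROI(f"{pname}_{k + 1:02d}", "midline") for k in range(count))
        out.append(PathwayDefinition(name=pname, rois=rois))
    return out


def build_group_covariance(layout, within: float, between: float) -> np.ndarray:
    """Block-exchangeable covariance: unit diagonal, ``within`` inside each
    pathway block, ``between`` everywhere else.

    For ``0 <= between <= within < 1`` this matrix is positive
    semi-definite by construction (it decomposes into a shared global
    factor, one factor per block, and idiosyncratic variance); the
    eigenvalue check guards any other parameter combination.
    """
    if not 0.0 <= between <= within < 1.0:
        raise ValueError(
            f"require 0 <= between <= within < 1, got between={between}, within={within}"
        )
    n = sum(count for _, count in layout)
    cov = np.full((n, n), float(between))
    offset = 0
    for _, count in layout:
        cov[offset : offset + count, offset : offset + count] = within
        offset += count
    np.fill_diagonal(cov, 1.0)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min < -1e-10:
        raise ValueError(
            f"covariance is not positive semi-definite: smallest eigenvalue {lam_min:.3e}"
        )
    return cov


def _group_rng(master_seed: int, group_name: str) -> np.random.Generator:
    # name-keyed stream: adding a group never perturbs existing groups
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, zlib.crc32(group_name.encode())])
    )


def generate_cohort(spec: SyntheticSpec) -> dict[str, SubjectMatrix]:
    """Draw one SubjectMatrix per group from the spec's block covariance.

    Rows are i.i.d. multivariate-normal subjects plus independent
    ``noise_sd`` Gaussian noise per ROI; identical specs (including seed)
    give bit-identical output.
    """
    roi_names = spec.roi_names
    out: dict[str, SubjectMatrix] = {}
    for gname, gsize, within in zip(spec.group_names, spec.group_sizes, spec.within_strength):
        cov = build_group_covariance(spec.pathway_layout, within, spec.between_strength)
        # small jitter keeps Cholesky valid in the PSD-but-singular corner
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        rng = _group_rng(spec.seed, gname)
        signal = rng.standard_normal((gsize, spec.n_rois)) @ chol.T
        noise = spec.noise_sd * rng.standard_normal((gsize, spec.n_rois))
        out[gname] = SubjectMatrix(
            values=signal + noise, roi_names=roi_names, group_label=gname
        )
    return out


def write_cohort(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write one CSV per group plus a JSON sidecar echoing the full spec."""
    from .atlas import write_subject_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    paths: dict[str, Path] = {}
    for gname, matrix in cohort.items():
        paths[gname] = write_subject_table(matrix, out_dir / f"group_{gname}.csv")
    sidecar = out_dir / "synthetic_spec.json"
    sidecar.write_text(json.dumps(spec.to_dict(), indent=2) + "\n", encoding="utf-8")
    paths["__spec__"] = sidecar
    return paths
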