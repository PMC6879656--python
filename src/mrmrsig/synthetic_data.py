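"""Two-class synthetic expression data with planted signal structure.

Three gene roles are planted:

* informative — class-conditional Gaussian with an additive mean shift of
  ``effect_size`` standard deviations between the two classes;
* redundant — noisy copies of an informative parent with within-class
  correlation ``within_block_correlation``;
* noise — label-independent Gaussians.

Train and test draws come from the same generative law and share gene ids;
an optional per-gene scale perturbation on the test draw mimics a platform
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel_io import NEGATIVE, POSITIVE, DatasetPair, ExpressionMatrix

INFORMATIVE = "informative"
REDUNDANT = "redundant"
NOISE = "noise"


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int = 60
    n_neg: int = 60
    n_informative: int = 5
    n_redundant_per_informative: int = 2
    n_noise: int = 200
    effect_size: float = 3.0
    within_block_correlation: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    test_scale_sd: float = 0.0  # per-gene log-scale perturbation on the test draw

    def validate(self) -> None:
        problems = []
        if self.n_pos < 2:
            problems.append(f"n_pos must be >= 2 (got {self.n_pos})")
        if self.n_neg < 2:
            problems.append(f"n_neg must be >= 2 (got {self.n_neg})")
        for name in ("n_informative", "n_redundant_per_informative", "n_noise"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0 (got {getattr(self, name)})")
        if not 0 <= self.within_block_correlation < 1:
            problems.append(
                f"within_block_correlation must be in [0, 1) (got {self.within_block_correlation})"
            )
        if self.noise_sd <= 0:
            problems.append(f"noise_sd must be > 0 (got {self.noise_sd})")
        if self.test_scale_sd < 0:
            problems.append(f"test_scale_sd must be >= 0 (got {self.test_scale_sd})")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @property
    def n_genes(self) -> int:
        return self.n_informative * (1 + self.n_redundant_per_informative) + self.n_noise


@dataclass
class SyntheticDataset:
    pair: DatasetPair
    roles: dict[str, str]  # gene_id -> INFORMATIVE | REDUNDANT | NOISE
    spec: SyntheticSpec

    def genes_with_role(self, *roles: str) -> set[str]:
        return {g for g, r in self.roles.items() if r in roles}


def _gene_ids(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    inf = [f"GINF{i:03d}" for i in range(1, spec.n_informative + 1)]
    red = [
        f"GRED{i:03d}_{j}"
        for i in range(1, spec.n_informative + 1)
        for j in range(1, spec.n_redundant_per_informative + 1)
    ]
    noi = [f"GNSE{i:04d}" for i in range(1, spec.n_noise + 1)]
    return inf, red, noi


def _draw(spec: SyntheticSpec, rng: np.random.Generator, prefix: str,
          scale: np.ndarray | None) -> ExpressionMatrix:
    n = spec.n_pos + spec.n_neg
    shift = np.r_[np.full(spec.n_pos, spec.effect_size / 2.0),
                  np.full(spec.n_neg, -spec.effect_size / 2.0)]
    inf_ids, red_ids, noi_ids = _gene_ids(spec)

    # alternate up/down regulation so class signal is not a constant profile offset
    direction = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    parents = rng.standard_normal((spec.n_informative, n)) \
        + direction[:, np.newaxis] * shift[np.newaxis, :]
    rho = spec.within_block_correlation
    blocks = [parents]
    if spec.n_redundant_per_informative > 0:
        eps = rng.standard_normal((len(red_ids), n))
        parent_rep = np.repeat(parents, spec.n_redundant_per_informative, axis=0)
        # weights chosen so the within-class correlation with the parent is rho
        blocks.append(rho * parent_rep + np.sqrt(1.0 - rho**2) * eps)
    blocks.append(rng.standard_normal((spec.n_noise, n)) * spec.noise_sd)
    values = np.vstack(blocks)

    gene_ids = inf_ids + red_ids + noi_ids
    if scale is not None:
        values = values * scale[:, np.newaxis]
    sample_ids = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    labels = {s: (POSITIVE if i < spec.n_pos else NEGATIVE) for i, s in enumerate(sample_ids)}
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                            values=values, labels=labels)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw an independent train/test pair from the spec; reproducible from seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    train = _draw(spec, rng, "TR", None)
    scale = None
    if spec.test_scale_sd > 0:
        scale = np.exp(rng.normal(0.0, spec.test_scale_sd, size=spec.n_genes))
    test = _draw(spec, rng, "TE", scale)
    inf_ids, red_ids, noi_ids = _gene_ids(spec)
    roles = {g: INFORMATIVE for g in inf_ids}
    roles.update({g: REDUNDANT for g in red_ids})
    roles.update({g: NOISE for g in noi_ids})
    return SyntheticDataset(pair=DatasetPair(train=train, test=test), roles=roles, spec=spec)


def write_truth(ds: SyntheticDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trole\n")
        for g in ds.pair.train.gene_ids:
            fh.write(f"{g}\t{ds.roles[g]}\n")
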