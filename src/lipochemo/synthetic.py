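"""Synthetic data with the statistical structure the analyses assume.

Two generators:

* :func:`make_descriptor_dataset` — a descriptor matrix (default 27
  compounds x 100 descriptors, mirroring the study's scale) in which a
  small known subset linearly drives the endpoint plus Gaussian noise.
  Descriptors can carry exchangeable block correlation, mimicking the
  heavy collinearity of computed molecular descriptors.  Used to
  exercise GA-PLS with a known ground truth.
* :func:`make_lipo_table` — a family of lipophilicity measures built as
  noisy affine transforms of one latent lipophilicity scale, the
  situation SRD/PCA/clustering presuppose: all measures estimate the
  same property with different scales and error levels.

Both are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDataset",
    "make_descriptor_dataset",
    "SyntheticLipoTable",
    "make_lipo_table",
]


@dataclass
class SyntheticDataset:
    X: pd.DataFrame
    y: pd.Series
    true_support: tuple[int, ...]
    true_beta: np.ndarray
    noise_sd: float
    seed: int | None

    @property
    def support_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns[list(self.true_support)])


def make_descriptor_dataset(n_compounds: int = 27, n_descriptors: int = 100,
                            n_informative: int = 5, noise_frac: float = 0.05,
                            correlation: float = 0.0,
                            seed=None) -> SyntheticDataset:
    """Descriptor matrix with a known informative subset.

    ``X[i,j] = sqrt(rho) * c_i + sqrt(1-rho) * e_ij`` gives exchangeable
    pairwise correlation ``rho`` between descriptors.  The endpoint is
    ``y = X[:, support] @ beta + eps`` with ``SD(eps) =
    noise_frac * SD(X @ beta)`` (population SD), beta nonzero only on a
    random support with magnitudes in [0.5, 2] and random signs.
    """
    if not 1 <= n_informative <= n_descriptors:
        raise ValueError("need 1 <= n_informative <= n_descriptors")
    if not 0 <= correlation < 1:
        raise ValueError("correlation must be in [0, 1)")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    common = rng.standard_normal((n_compounds, 1))
    indep = rng.standard_normal((n_compounds, n_descriptors))
    X = np.sqrt(correlation) * common + np.sqrt(1 - correlation) * indep
    support = tuple(sorted(rng.choice(n_descriptors, size=n_informative,
                                      replace=False).tolist()))
    beta = rng.uniform(0.5, 2.0, size=n_informative)
    beta *= rng.choice([-1.0, 1.0], size=n_informative)
    signal = X[:, list(support)] @ beta
    noise_sd = float(noise_frac * signal.std())
    y = signal + rng.normal(0.0, noise_sd, size=n_compounds) if noise_sd > 0 \
        else signal
    ids = pd.Index([str(i + 1) for i in range(n_compounds)], name="compound")
    names = [f"D{j + 1:04d}" for j in range(n_descriptors)]
    Xdf = pd.DataFrame(X, index=ids, columns=names)
    Xdf.attrs["provenance"] = "synthetic"
    return SyntheticDataset(Xdf, pd.Series(y, index=ids, name="y"),
                            support, beta, noise_sd, seed)


@dataclass
class SyntheticLipoTable:
    table: pd.DataFrame
    latent: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    noise_sds: np.ndarray
    seed: int | None


def make_lipo_table(n_compounds: int = 27, n_measures: int = 12,
                    noise_sds=None, slopes=None, intercepts=None,
                    seed=None) -> SyntheticLipoTable:
    """Measures as noisy affine transforms of one latent lipophilicity.

    ``measure_j = a_j + b_j * latent + N(0, noise_sd_j)`` with positive
    slopes ``b_j``.  The latent scale is standard normal.  Defaults draw
    slopes from U(0.5, 2), intercepts from N(0, 1), and use noise SD 0.3
    for every measure (about a third of the latent spread — comparable
    to the disagreement between real logP estimators).
    """
    rng = np.random.default_rng(seed)
    if noise_sds is None:
        noise_sds = np.full(n_measures, 0.3)
    noise_sds = np.asarray(noise_sds, dtype=float)
    if noise_sds.size != n_measures:
        raise ValueError("len(noise_sds) must equal n_measures")
    if np.any(noise_sds < 0):
        raise ValueError("noise SDs must be >= 0")
    latent = rng.standard_normal(n_compounds)
    slopes = rng.uniform(0.5, 2.0, size=n_measures) if slopes is None \
        else np.asarray(slopes, dtype=float)
    if np.any(slopes <= 0):
        raise ValueError("slopes must be positive")
    intercepts = rng.normal(0.0, 1.0, size=n_measures) if intercepts is None \
        else np.asarray(intercepts, dtype=float)
    values = intercepts + np.outer(latent, slopes) \
        + rng.normal(0.0, 1.0, size=(n_compounds, n_measures)) * noise_sds
    ids = pd.Index([str(i + 1) for i in range(n_compounds)], name="compound")
    cols = [f"M{j + 1:02d}" for j in range(n_measures)]
    return SyntheticLipoTable(pd.DataFrame(values, index=ids, columns=cols),
                              latent, slopes, intercepts, noise_sds, seed)
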