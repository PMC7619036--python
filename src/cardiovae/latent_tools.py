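"""Latent-space analysis and virtual heart population generation.

Component traversal decodes a sweep of one latent component while holding
the others at the dataset's mean posterior value, exposing which shape
factor (heart size, elongation, basal tilt, ...) the component encodes.
The per-component effect size is the Chamfer distance between the decoded
anatomies at -2 SD and +2 SD of the component, averaged over channels.
Virtual populations are generated by sampling the latent space and
decoding: by default from a Gaussian moment-matched to a reference
dataset's aggregate posterior, or from the N(0, I) prior when no
reference is given.
"""

from __future__ import annotations

import numpy as np

from . import point_vae, shape_metrics
from .synthetic_anatomy import AnatomySample, MultiClassPointCloud

__all__ = [
    "posterior_means", "traverse_component", "component_effect_size",
    "sample_virtual_population", "decoded_to_sample",
]


def posterior_means(model, dataset) -> np.ndarray:
    """Matrix of posterior means mu, one row per dataset subject."""
    return np.asarray([point_vae.encode(s, model).mu for s in dataset])


def _traversal_stats(model, dataset):
    mus = posterior_means(model, dataset)
    return mus.mean(axis=0), mus.std(axis=0, ddof=0)


def traverse_component(model, dataset, component: int, values,
                       stats=None) -> list[point_vae.DecodedAnatomy]:
    """Decode a sweep of one latent component in SD multiples.

    The latent vector equals the dataset's mean posterior mu except at
    ``component``, which is set to mean + value * SD of that component's
    posterior means.  ``stats`` optionally supplies precomputed
    (mean, SD) arrays to avoid re-encoding the dataset.
    """
    latent_dim = model.config.latent_dim
    if not 0 <= component < latent_dim:
        raise IndexError(
            f"component {component} out of range for latent dim {latent_dim}")
    mean, sd = _traversal_stats(model, dataset) if stats is None else stats
    out = []
    for v in values:
        z = mean.copy()
        z[component] = mean[component] + float(v) * sd[component]
        out.append(point_vae.decode(z, model))
    return out


def component_effect_size(model, dataset, component: int,
                          sd_multiple: float = 2.0, stats=None) -> float:
    """Chamfer distance (mm) between the -2 SD and +2 SD decodes of one
    component, averaged over the decoder's output channels."""
    lo, hi = traverse_component(model, dataset, component,
                                [-sd_multiple, +sd_multiple], stats=stats)
    n_ch = lo.dense.shape[2]
    cds = [shape_metrics.chamfer_distance(lo.dense[:, :, k], hi.dense[:, :, k])
           for k in range(n_ch)]
    return float(np.mean(cds))


def all_component_effect_sizes(model, dataset, sd_multiple: float = 2.0) -> np.ndarray:
    """Effect sizes of every latent component (shared dataset encoding)."""
    stats = _traversal_stats(model, dataset)
    return np.asarray([
        component_effect_size(model, dataset, i, sd_multiple, stats=stats)
        for i in range(model.config.latent_dim)
    ])


def decoded_to_sample(dec: point_vae.DecodedAnatomy, subject_id: str,
                      n_classes: int = 3, phases: int = 2) -> AnatomySample:
    """Reassemble decoder channels into a labeled ED/ES anatomy sample."""
    clouds = []
    p = dec.dense.shape[0]
    for ph, phase in enumerate(["ED", "ES"][:phases]):
        pts = [dec.dense[:, :, ph * n_classes + cl] for cl in range(n_classes)]
        labels = np.concatenate([np.full(p, cl + 1) for cl in range(n_classes)])
        clouds.append(MultiClassPointCloud(points=np.vstack(pts),
                                           labels=labels, phase=phase))
    return AnatomySample(subject_id=subject_id, ed=clouds[0], es=clouds[1],
                         group="control")


def sample_virtual_population(model, n: int, seed: int, dataset=None,
                              use_prior: bool = False) -> list[AnatomySample]:
    """Generate n virtual subjects by sampling latent space and decoding.

    When ``dataset`` is given (the recommended mode), z is drawn from a
    Gaussian moment-matched to the dataset's aggregate posterior (mean and
    covariance of the posterior means plus the mean posterior variance) —
    the latent-space distribution that actually generates the encoded
    population.  Without a dataset, or with ``use_prior=True``, z ~ N(0, I)
    (the VAE prior); at short training budgets the aggregate posterior is
    measurably narrower than the prior, so prior samples can fall outside
    the region the decoder was trained on.  Subjects are independent given
    the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    latent = model.config.latent_dim
    if dataset is not None and not use_prior:
        codes = [point_vae.encode(s, model) for s in dataset]
        mus = np.asarray([c.mu for c in codes])
        sig2 = np.mean([c.sigma**2 for c in codes], axis=0)
        mean = mus.mean(axis=0)
        cov = np.cov(mus.T) + np.diag(sig2)
        zs = rng.multivariate_normal(mean, cov, size=n)
    else:
        zs = rng.standard_normal((n, latent))
    return [
        decoded_to_sample(point_vae.decode(z, model), f"virtual-{seed}-{i}",
                          n_classes=model.config.n_classes,
                          phases=model.config.phases)
        for i, z in enumerate(zs)
    ]
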