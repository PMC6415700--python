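"""Random model generation for testing and calibration studies.

Rates are drawn log-uniformly over decade ranges typical of naive T-cell
recirculation: migration in ``10^-3 .. 10^0 min^-1`` and division/death
in ``10^-6 .. 10^-3 min^-1``, so migration is faster than demography by
the same margin as in the published data.  The ``regime`` argument
enforces (by rejection) whether the emitted models satisfy the
non-explosion conditions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .models import StarModel, check_finiteness, validate
from .io import save_model

__all__ = ["random_star_model", "generate_fixtures"]

MIGRATION_DECADES = (1e-3, 1e0)
DEMOGRAPHY_DECADES = (1e-6, 1e-3)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def random_star_model(
    rng: np.random.Generator | int | None = None,
    M: int = 5,
    regime: str = "mixed",
    max_tries: int = 10_000,
) -> StarModel:
    """Draw one random validated star model.

    ``regime``: ``"subcritical"`` (non-explosion conditions enforced),
    ``"supercritical"`` (at least one condition violated) or ``"mixed"``
    (no constraint).
    """
    if regime not in ("subcritical", "supercritical", "mixed"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for _ in range(max_tries):
        model = StarModel(
            xi_in=_log_uniform(rng, *MIGRATION_DECADES, size=M),
            xi_out=_log_uniform(rng, *MIGRATION_DECADES, size=M),
            mu=_log_uniform(rng, *DEMOGRAPHY_DECADES, size=M),
            lam=_log_uniform(rng, *DEMOGRAPHY_DECADES, size=M),
            mu_B=float(_log_uniform(rng, *DEMOGRAPHY_DECADES)),
            lam_B=float(_log_uniform(rng, *DEMOGRAPHY_DECADES)),
        )
        validate(model)
        if regime == "mixed":
            return model
        ok = check_finiteness(model).ok
        if (regime == "subcritical") == ok:
            return model
    raise RuntimeError(
        f"could not draw a {regime} model in {max_tries} tries"
    )  # pragma: no cover


def generate_fixtures(
    n_models: int,
    M_range: tuple[int, int] = (1, 5),
    seed: int = 0,
    regime: str = "mixed",
    out_dir: str | Path | None = None,
) -> list[StarModel]:
    """Draw ``n_models`` random models; optionally write them as YAML files.

    Reproducible: the same seed yields identical models (and identical
    files, named ``model_000.yaml``...).
    """
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        M = int(rng.integers(M_range[0], M_range[1] + 1))
        models.append(random_star_model(rng, M=M, regime=regime))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, model in enumerate(models):
            save_model(model, out_dir / f"model_{k:03d}.yaml")
    return models
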