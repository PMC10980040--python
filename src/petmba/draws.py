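"""Posterior draw container shared by the hierarchical models."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws"]


class PosteriorDraws:
    """Named posterior samples with chain structure.

    Each entry maps a parameter name to an array of shape
    (n_chains, n_draws).  Convergence diagnostics (split R-hat, bulk ESS)
    are computed through arviz on request and any warnings raised during
    fitting are carried in ``warnings``.
    """

    def __init__(self, draws: dict, meta: dict | None = None, warnings: list | None = None):
        if not draws:
            raise ValueError("empty draws")
        shapes = {v.shape for v in draws.values()}
        if len(shapes) != 1:
            raise ValueError("all parameters must share (n_chains, n_draws) shape")
        ((self.n_chains, self.n_draws),) = shapes
        for name, v in draws.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite draws for {name!r}")
        self._draws = dict(draws)
        self.meta = meta or {}
        self.warnings = list(warnings or [])

    @property
    def names(self) -> list:
        return list(self._draws)

    def __contains__(self, name: str) -> bool:
        return name in self._draws

    def array(self, name: str) -> np.ndarray:
        """Draws with chain structure, shape (n_chains, n_draws)."""
        if name not in self._draws:
            raise KeyError(
                f"unknown parameter {name!r}; available: {', '.join(sorted(self._draws)[:20])} ..."
            )
        return self._draws[name]

    def get(self, name: str) -> np.ndarray:
        """Flattened draws across chains."""
        return self.array(name).reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def select(self, prefix: str) -> dict:
        """All parameters whose name starts with ``prefix``."""
        return {k: v for k, v in self._draws.items() if k.startswith(prefix)}

    def rhat(self, name: str) -> float:
        import arviz as az

        return float(az.rhat(self.array(name)))

    def ess(self, name: str) -> float:
        import arviz as az

        return float(az.ess(self.array(name)))

    def convergence_report(self, names: list | None = None, rhat_limit: float = 1.05) -> dict:
        """R-hat and bulk ESS for the selected (default: all fixed-effect-like)
        parameters; flags any R-hat above ``rhat_limit``."""
        if names is None:
            names = [n for n in self.names if not n.startswith(("theta[", "u[", "lambda"))]
        report = {}
        flagged = []
        for n in names:
            r = self.rhat(n) if self.n_chains > 1 else float("nan")
            e = self.ess(n)
            report[n] = {"rhat": r, "ess_bulk": e}
            if np.isfinite(r) and r > rhat_limit:
                flagged.append(n)
        return {"parameters": report, "rhat_limit": rhat_limit, "flagged": flagged}

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table (chain, draw, parameter, value)."""
        frames = []
        for name, arr in self._draws.items():
            c, d = np.meshgrid(np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "draw": d.ravel(),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_tidy(cls, table: pd.DataFrame, meta: dict | None = None) -> "PosteriorDraws":
        draws = {}
        for name, sub in table.groupby("parameter", sort=False):
            piv = sub.pivot(index="chain", columns="draw", values="value")
            draws[name] = piv.values
        return cls(draws, meta=meta)
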