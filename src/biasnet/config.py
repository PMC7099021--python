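"""Model configuration.

A single :class:`ModelConfig` collects every scalar parameter of the biased
social-learning model:

``n``
    number of agents.
``k``
    degree of the network (exact degree for ``k-regular``; mean degree for the
    other topologies).
``f``
    fraction of biased agents, ``0 <= f <= 1``.
``q``
    confirmation-bias parameter: the probability with which a biased agent
    rejects an incongruent incoming signal and replaces it with a congruent
    one, ``0 <= q <= 1``.
``p``
    informativeness of the initial signals, ``Prob(s_i = +1 | X = +1)``; the
    ground truth is fixed to ``X = +1``, so signals must be informative,
    ``1/2 < p < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

TOPOLOGIES = ("k-regular", "erdos-renyi", "barabasi-albert", "small-world")


@dataclass(frozen=True)
class ModelConfig:
    """All scalar parameters of a model run.

    Defaults follow the reference parameterisation used throughout the
    package's worked examples (n=1000, k=6, f=0.4, p=0.51 on a random
    regular graph).
    """

    n: int = 1000
    k: int = 6
    f: float = 0.4
    q: float = 0.6
    p: float = 0.51
    topology: str = "k-regular"
    seed: int = 0
    tol: float = 1e-10
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int,)) or self.n <= 0:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if not isinstance(self.k, (int,)) or self.k <= 0:
            raise ValueError(f"k must be a positive integer, got {self.k!r}")
        if self.k >= self.n:
            raise ValueError(f"k must be smaller than n (k={self.k}, n={self.n})")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        validate_p(self.p)
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; expected one of {TOPOLOGIES}"
            )
        if self.topology == "k-regular" and (self.n * self.k) % 2 != 0:
            raise ValueError(
                f"a k-regular graph needs n*k even (n={self.n}, k={self.k})"
            )
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter <= 0:
            raise ValueError(f"max_iter must be positive, got {self.max_iter}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def replace(self, **kwargs: Any) -> "ModelConfig":
        d = self.to_dict()
        d.update(kwargs)
        return ModelConfig(**d)


def validate_p(p: float) -> None:
    """Reject uninformative signal probabilities.

    Signals must carry information about the ground truth: ``p`` is
    ``Prob(s_i = +1 | X = +1)`` and the model requires ``1/2 < p < 1``.
    """
    if not (0.5 < p < 1.0):
        raise ValueError(
            f"signal informativeness p must satisfy 1/2 < p < 1, got {p}; "
            "p <= 1/2 would make initial signals uninformative of the ground truth"
        )
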