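"""Run configuration: a flat key-value record tying the pipeline together.

The on-disk format is one ``key = value`` pair per line; ``#`` starts a
comment.  Every field has a documented default, and CLI flags override file
values.  Booleans serialise as ``true``/``false``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .exceptions import InvalidParameterError
from .frfcm import FRFCMParams
from .nlm import NLMParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end run."""

    # pipeline
    method: str = "fanlm"            # fanlm | nlm
    selection_mode: str = "local"    # local | global window choice
    fcm_stage: str = "post"          # post | first | off
    seed: int = 0
    log_level: str = "info"

    # NLM
    patch_radius: int = 2
    h_factor: float = 1.2
    kernel_std_a: float = 1.0
    self_weight: str = "max"
    window_small: int = 7
    window_medium: int = 13
    window_large: int = 21
    fixed_window: int = 13           # used when method = nlm

    # noise estimator
    wavelet: str = "haar"
    mask: str = "none"               # none | otsu
    estimator_eps: float = 1.0e-8
    estimator_max_iter: int = 500
    correction: str = "multiply"     # multiply | divide

    # FRFCM
    n_clusters: int = 4
    fuzzifier: float = 2.0
    se_radius: int = 3
    membership_filter_side: int = 3
    fcm_max_iter: int = 100
    fcm_tol: float = 1.0e-5
    n_bins: int = 256

    def nlm_params(self) -> NLMParams:
        return NLMParams(
            patch_radius=self.patch_radius, h=None, h_factor=self.h_factor,
            kernel_std_a=self.kernel_std_a, window_small=self.window_small,
            window_medium=self.window_medium, window_large=self.window_large,
            self_weight=self.self_weight,
        )

    def frfcm_params(self) -> FRFCMParams:
        return FRFCMParams(
            n_clusters=self.n_clusters, fuzzifier=self.fuzzifier,
            se_radius=self.se_radius,
            membership_filter_side=self.membership_filter_side,
            max_iter=self.fcm_max_iter, tol=self.fcm_tol,
            n_bins=self.n_bins, seed=self.seed,
        )

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, bool):
                value = "true" if value else "false"
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidParameterError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}"
                )
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise InvalidParameterError(
                    f"{path}:{lineno}: unknown config key {key!r}"
                )
            default = getattr(defaults, key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
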