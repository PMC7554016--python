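"""Model parameters for the motion-vision pathway model.

The defaults reproduce the standard operating point of the model: a 30 fps
video stream, change persistence over two frames, fast-depolarising /
slow-repolarising adaptation constants of 1 ms and 100 ms, a centre-surround
difference-of-Gaussians with standard deviations (2, 4) px, and ensembles of
four same-polarity correlators per pixel and direction with sampling distance
4 px and distance-dependent delay between 10 and 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

import yaml

__all__ = ["ModelParams"]


@dataclass
class ModelParams:
    """All tunable parameters of the visual-system model.

    Parameters
    ----------
    fps : float
        Frame rate of the input stream in frames/second.  The inter-frame
        interval ``tau_i = 1000 / fps`` ms is derived from it, never set
        independently.
    n_p : int
        Number of frames over which a brightness change persists (decays)
        in the photoreceptor layer.  0 disables persistence.
    tau_1, tau_2 : float
        Fast-depolarising and slow-repolarising time constants of the FDSR
        adaptation, in ms.  ``tau_1 < tau_2`` is required.
    sigma_e, sigma_i : float
        Standard deviations (px) of the excitatory centre and inhibitory
        surround Gaussians of the vDoG.  The surround must be twice the
        centre (``sigma_i == 2 * sigma_e``).
    sd : int
        Sampling distance in px between pair-wise correlators.
    n_c : int
        Number of correlated neighbour cells per pixel and direction; the
        correlator lattice is ``{sd, 2*sd, ..., n_c*sd}``.
    tau_s_min, tau_s_max : float
        Bounds of the distance-dependent dynamic delay in ms.  The nearest
        pair receives ``tau_s_max``, the farthest ``tau_s_min``.
    k : float
        Scale coefficient of the output sigmoid; the raw wide-field sum is
        divided by ``C * R * k`` before activation.  Tuned for luminance on
        the raw 0-255 scale; rescaling luminance requires retuning ``k``.
    enable_vdog, enable_fdsr : bool
        Ablation switches.  Disabling the vDoG makes the spatial stage an
        identity pass-through; disabling the FDSR sets ``M := L``.
    fdsr_recursive, delay_recursive : bool
        The adaptation and delay recursions can mix the current sample with
        the previous *raw* sample (a 2-tap FIR) or with the previous trace
        (a true first-order IIR low-pass).  The FDSR defaults to the FIR
        form.  The correlator delay defaults to the IIR form: its dynamic
        latency runs up to 200 ms (six frames at 30 fps), which a 2-tap
        blend cannot represent, and only the IIR trace gives the ensembles
        their tuning to slow image motion.
    mixed_sign_policy : str
        What the vDoG emits where centre and surround responses disagree in
        sign.  Only ``"zero"`` is implemented: ambiguous centre-surround
        polarity carries no reliable ON/OFF label.
    """

    fps: float = 30.0
    n_p: int = 2
    tau_1: float = 1.0
    tau_2: float = 100.0
    sigma_e: float = 2.0
    sigma_i: float = 4.0
    sd: int = 4
    n_c: int = 4
    tau_s_min: float = 10.0
    tau_s_max: float = 200.0
    k: float = 0.01
    enable_vdog: bool = True
    enable_fdsr: bool = True
    fdsr_recursive: bool = False
    delay_recursive: bool = True
    mixed_sign_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_p < 0:
            raise ValueError("n_p must be >= 0")
        if not self.tau_1 < self.tau_2:
            raise ValueError("tau_1 must be smaller than tau_2")
        if self.sigma_e <= 0 or self.sigma_i != 2 * self.sigma_e:
            raise ValueError("sigma_i must equal 2 * sigma_e (centre-surround ratio)")
        if self.sd < 1 or self.n_c < 1:
            raise ValueError("sd and n_c must be >= 1")
        if not self.tau_s_min < self.tau_s_max:
            raise ValueError("tau_s_min must be smaller than tau_s_max")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.mixed_sign_policy != "zero":
            raise ValueError("only mixed_sign_policy='zero' is implemented")

    @property
    def tau_i(self) -> float:
        """Inter-frame interval in ms, derived from the frame rate."""
        return 1000.0 / self.fps

    @property
    def alpha_1(self) -> float:
        """Fast-depolarising smoothing coefficient tau_i / (tau_1 + tau_i)."""
        return self.tau_i / (self.tau_1 + self.tau_i)

    @property
    def alpha_2(self) -> float:
        """Slow-repolarising smoothing coefficient tau_i / (tau_2 + tau_i)."""
        return self.tau_i / (self.tau_2 + self.tau_i)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
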