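"""Experiment configuration: schema-validated, fully defaulted per task.

Configs are plain YAML mappings; unknown keys are rejected and every field
has a task-appropriate default, so an empty file yields the default
protocol for the named task.  The four network variants (clustered or
unclustered recurrent structure, plastic or static input projections) are
pure configuration — no code changes.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import ConfigurationError

__all__ = ["ExperimentConfig", "validate_config", "smoke_preset"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSection(_Section):
    """Representation-layer structure and membrane constants."""

    n_exc: int = 400
    n_inh: int = 96
    n_clusters: int = 8
    conn_prob: float = 0.2
    j_plus: float = 8.0
    j_plus_inh: float = 1.5
    # base weight magnitudes (pA) at the 5000-neuron reference size
    j_ee: float = 2.0
    j_ei: float = 27.0
    j_ie: float = 6.0
    j_ii: float = 9.0
    tau_m_exc: float = 20.0
    tau_m_inh: float = 10.0
    C: float = 250.0
    V_th: float = 20.0
    V_reset: float = 0.0
    t_ref: float = 2.0
    tau_s: float = 5.0
    I_bias_exc: float = 100.0
    I_bias_inh: float = 400.0
    dt: float = 0.1


class InputPlasticitySection(_Section):
    """The unsupervised Hebbian/synaptic-scaling rule on input projections."""

    enabled: bool = True
    mu: float = 2.5e-6  # per update
    kappa: float = 0.8
    F_T: float = 3.0
    w_min: float = 0.0
    w_max: float = 500.0
    update_interval: float = 5.0  # ms
    init_low: float = 60.0
    init_high: float = 180.0
    conn_prob: float = 0.1
    targets: Literal["all", "exc"] = "exc"


class OutputPlasticitySection(_Section):
    """The dopamine-modulated three-factor rule on output projections."""

    mu: float = 1.5e-4  # per update
    kappa: float = 0.05
    F_T: float = 12.0
    w_min: float = 0.0
    w_max: float = 50.0
    init_low: float = 4.0
    init_high: float = 8.0
    j_lateral: float = 1000.0
    bg_rate: float = 2000.0
    w_bg: float = 20.0
    tau_dec: float = 50.0


class CriticSection(_Section):
    """Actor-critic circuit used by the closed-loop control task."""

    n_critic: int = 20
    n_rpe: int = 1000
    delay_exc: float = 1.0
    delay_inh: float = 20.0
    tau_r: float = 1.0
    critic_base: float = 20.0
    rpe_base: float = 1000.0
    d_gain: float = 1.0
    tau_v: float = 100.0
    reward_gain: float = 100.0  # D units per unit of environment reward
    mu: float = 5e-6
    kappa: float = 0.02
    F_T: float = 15.0
    w_max: float = 10.0


class XorSection(_Section):
    """Logic-gate protocol parameters."""

    n_rep: int = 3
    j_wta: float = 1000.0
    noise_rate: float = 1000.0
    w_noise: float = 8.0
    init_low: float = 33.33
    init_high: float = 66.66
    mu: float = 1e-6
    kappa: float = 0.3
    F_T: float = 5.0
    w_max: float = 500.0
    total_s: float = 500.0
    record_s: float = 50.0
    tau_readout: float = 30.0
    on_rate: float = 1000.0
    off_rate: float = 10.0


class DigitsSection(_Section):
    """3-class digit classification protocol parameters."""

    n_train: int = 200
    n_test: int = 0
    F_max: float = 60.0
    present_ms: float = 500.0
    feedback_ms: float = 100.0
    da_base_rate: float = 100.0
    synthetic: bool = True
    mnist_images: str | None = None
    mnist_labels: str | None = None


class MountainCarSection(_Section):
    """Closed-loop control protocol parameters."""

    n_episodes: int = 5
    max_steps: int = 500  # safety cap per episode (the goal is the only true end)
    env_step_ms: float = 20.0
    n_rf: int = 200
    rf_sigma: float = 0.05
    rf_peak_rate: float = 35.0


class ExperimentConfig(_Section):
    """One task run: network variant, all module parameters, seed."""

    task: Literal["xor", "digits", "mountaincar"]
    seed: int = 1
    clustered: bool = True
    network: NetworkSection = Field(default_factory=NetworkSection)
    input_plasticity: InputPlasticitySection = Field(
        default_factory=InputPlasticitySection
    )
    output_plasticity: OutputPlasticitySection = Field(
        default_factory=OutputPlasticitySection
    )
    critic: CriticSection = Field(default_factory=CriticSection)
    xor: XorSection = Field(default_factory=XorSection)
    digits: DigitsSection = Field(default_factory=DigitsSection)
    mountaincar: MountainCarSection = Field(default_factory=MountainCarSection)

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        net = self.network
        n_c = self.n_clusters_effective
        if n_c < 1:
            raise ValueError("n_clusters must be non-negative")
        if net.n_exc % n_c or net.n_inh % n_c:
            raise ValueError(
                f"n_exc={net.n_exc} and n_inh={net.n_inh} must be divisible by "
                f"n_clusters={n_c}"
            )
        return self

    @property
    def n_clusters_effective(self) -> int:
        # n_clusters=0 is the conventional label for the unclustered condition
        if not self.clustered or self.network.n_clusters == 0:
            return 1
        return self.network.n_clusters


def validate_config(raw: str, task: str | None = None) -> ExperimentConfig:
    """Parse and validate a YAML config document.

    An empty document yields the full default config for ``task``; unknown
    keys, wrong types and violated invariants raise ConfigurationError with
    the offending key named.
    """
    try:
        data = yaml.safe_load(raw) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    if task is not None:
        data.setdefault("task", task)
    try:
        return ExperimentConfig(**data)
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc


def smoke_preset(cfg: ExperimentConfig) -> ExperimentConfig:
    """Shrink a config for quick runs (shorter durations, fewer trials)."""
    return cfg.model_copy(
        update={
            "xor": cfg.xor.model_copy(update={"total_s": 50.0, "record_s": 10.0}),
            "digits": cfg.digits.model_copy(update={"n_train": 30, "n_test": 0}),
            "mountaincar": cfg.mountaincar.model_copy(
                update={"n_episodes": 1, "max_steps": 100}
            ),
        }
    )
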