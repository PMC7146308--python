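"""Power, lifetime and accuracy/lifetime trade-off model.

Device lifetime is ``T = E_BAT / (P_I + P_A + P_G + P_MCU)``: battery budget
over the sum of idle power, average accelerometer and gyroscope power, and
average microcontroller power.  P_MCU is built from per-event energies
(micro-joules per SPI transfer, per feature extracted, per classifier
executed, per radio advertisement) times the frequency of those events:

* raw streaming: every sample is read over SPI, copied to the radio buffer
  and broadcast, at the 17 Hz sampling rate;
* on-board classification: one FIFO read per two classifications, feature
  extraction and the two classifier stages per window, and a single 4-byte
  advertisement per classification, at the 0.87 Hz classification rate.

How often each Stage-2 classifier (and hence the gyroscope) is engaged is
weighted by the fraction of the day an average person spends in each energy
band (occupancy weights 0.808 / 0.188 / 0.004 for Sedentary / Moderate /
Rigorous).

Per-event energies default to bench measurements of the reference hardware
(MC3672 accelerometer, ICM20948 gyroscope, CC2640R2 MCU, BLE radio at
0 dBm).  The average sensor and idle powers P_I, P_A, P_G are configuration
inputs — they depend on hardware duty-cycling details outside this model —
so total power and lifetime are model outputs whose absolute level follows
the configured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from .hierarchy import as_percent, weighted_accuracy

SECONDS_PER_DAY = 86400.0

#: default event rates (Hz)
RAW_EVENT_RATE_HZ = 17.0       # per-sample streaming, gyro sampling rate
EML_EVENT_RATE_HZ = 0.87      # classification rate (two per FIFO refill)


def _default_feature_energies() -> dict[str, float]:
    # uJ per feature over a 32-sample window
    return {"ima": 8.14, "median": 4.10, "var": 1.21, "mean": 0.87,
            "max": 0.16, "min": 0.16}


def _default_classifier_energies() -> dict[str, float]:
    # uJ per execution
    return {"stage1": 0.88, "sedentary": 0.90, "moderate_acc": 0.79,
            "moderate_gyr": 1.41, "rigorous": 0.92}


@dataclass
class EnergyTable:
    """Per-event energies (uJ), sensor/idle powers (uW) and battery budget (J)."""

    e_fifo_read_accel: float = 7.35   # 32-sample FIFO read, accelerometer
    e_fifo_read_gyro: float = 5.47    # 32-sample FIFO read, gyroscope
    e_sample_accel: float = 0.50      # single-sample SPI read, accelerometer
    e_sample_gyro: float = 0.37       # single-sample SPI read, gyroscope
    e_fifo_convert: float = 0.48      # FIFO bytes -> 16-bit triaxial ints
    e_data_prep: float = 12.01        # copy to radio transmission buffer
    e_ble_adv: float = 73.16          # one BLE advertisement at 0 dBm
    feature_energies: dict[str, float] = field(
        default_factory=_default_feature_energies)
    classifier_energies: dict[str, float] = field(
        default_factory=_default_classifier_energies)
    e_bat_j: float = 1332.0           # battery budget
    p_idle_uw: float = 3.3            # system idle power
    p_accel_uw: float = 3.0           # average accelerometer power
    p_gyro_uw: float = 3900.0         # average gyroscope power (always on)

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"negative energy/power in {name}")

    def feature_cost(self, feature_name: str) -> float:
        """uJ to extract one named feature (same per-stat cost per sensor)."""
        if feature_name == "ima":
            return self.feature_energies["ima"]
        stat = feature_name.split("_")[1]
        return self.feature_energies[stat]


@dataclass(frozen=True)
class OccupancyWeights:
    """Fractions of the day spent in each energy band; must sum to 1."""

    sedentary: float = 0.808
    moderate: float = 0.188
    rigorous: float = 0.004

    def __post_init__(self) -> None:
        if abs(self.sedentary + self.moderate + self.rigorous - 1.0) > 1e-9:
            raise ValueError("occupancy weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sedentary, self.moderate, self.rigorous)


@dataclass
class PowerBudget:
    """Decomposed average power (uW) and the implied lifetime (days)."""

    p_idle_uw: float
    p_accel_uw: float
    p_gyro_uw: float
    p_mcu_uw: float
    e_bat_j: float

    @property
    def total_uw(self) -> float:
        return self.p_idle_uw + self.p_accel_uw + self.p_gyro_uw + self.p_mcu_uw

    @property
    def lifetime_days(self) -> float:
        return lifetime(self.e_bat_j, self.total_uw)


def p_mcu_raw(table: EnergyTable, f_irq: float = RAW_EVENT_RATE_HZ,
              use_gyro: bool = False) -> float:
    """Average MCU power (uW) when streaming raw samples over the air.

    Per sample: single-sample SPI read(s), copy to the radio buffer and one
    advertisement, all at ``f_irq``.
    """
    if f_irq <= 0:
        raise ValueError("f_irq must be positive")
    e = table.e_sample_accel + table.e_data_prep + table.e_ble_adv
    if use_gyro:
        e += table.e_sample_gyro
    return e * f_irq


def p_mcu_eml(table: EnergyTable, feature_set,
              stage2_mix: OccupancyWeights,
              f_irq: float = EML_EVENT_RATE_HZ,
              use_gyro: bool = False,
              gyro_duty: float = 1.0) -> float:
    """Average MCU power (uW) of the on-board classification pipeline.

    ``(E_T + sum_i E_Fi + E_S1 + E_S2) * f_irq`` with
    ``E_T = E_FIFO_A/2 + E_FIFO_G/2 + E_BLE + E_DATA`` — the FIFO-read terms
    are halved because, with 50% window overlap, a FIFO refill serves two
    classifications.  ``feature_set`` maps feature names to the fraction of
    windows on which each is extracted (a plain list means always); gyro
    terms are scaled by ``gyro_duty`` (the fraction of time the gyro is on;
    1.0 for an always-on gyro, the Moderate occupancy when gated) and vanish
    when ``use_gyro`` is false.  E_S2 is the occupancy-weighted mean of the
    engaged Stage-2 classifier energies, with the Moderate branch priced as
    the accel+gyro model when ``use_gyro`` is set.
    """
    if f_irq <= 0:
        raise ValueError("f_irq must be positive")
    e_t = table.e_fifo_read_accel / 2.0 + table.e_ble_adv + table.e_data_prep
    if use_gyro:
        e_t += gyro_duty * table.e_fifo_read_gyro / 2.0

    if not isinstance(feature_set, dict):
        feature_set = {name: 1.0 for name in feature_set}
    e_f = 0.0
    for name, duty in feature_set.items():
        scale = gyro_duty * duty if name.startswith("gyr_") else duty
        e_f += scale * table.feature_cost(name)

    ce = table.classifier_energies
    w = stage2_mix.as_tuple()
    moderate = ce["moderate_gyr"] if use_gyro else ce["moderate_acc"]
    e_s2 = w[0] * ce["sedentary"] + w[1] * moderate + w[2] * ce["rigorous"]

    return (e_t + e_f + ce["stage1"] + e_s2) * f_irq


def lifetime(e_bat_j: float, total_power_uw: float) -> float:
    """Battery lifetime in days for a budget in J and a draw in uW."""
    if total_power_uw <= 0:
        raise ValueError("total power must be positive")
    seconds = e_bat_j / (total_power_uw * 1e-6)
    return seconds / SECONDS_PER_DAY


@dataclass
class OperatingPoint:
    """One configuration row of the accuracy/lifetime trade-off.

    ``mode`` is ``"raw"`` (stream every sample) or ``"eml"`` (on-board
    classification).  ``a_s1`` / ``a_s2`` are the per-stage accuracies
    (fractions); ``feature_set`` maps the features the eml pipeline extracts
    to their per-window duty fraction.
    """

    label: str
    mode: str  # "raw" | "eml"
    a_s1: float
    a_s2: tuple[float, float, float]
    use_gyro: bool = False
    feature_set: dict = field(default_factory=dict)
    weights: OccupancyWeights = field(default_factory=OccupancyWeights)
    f_irq: float | None = None

    def power(self, table: EnergyTable) -> PowerBudget:
        if self.mode == "raw":
            p_mcu = p_mcu_raw(table, self.f_irq or RAW_EVENT_RATE_HZ,
                              self.use_gyro)
            p_gyro = table.p_gyro_uw if self.use_gyro else 0.0
        elif self.mode == "eml":
            # gated gyro: on only while Stage 1 reports Moderate
            duty = self.weights.moderate if self.use_gyro else 0.0
            p_mcu = p_mcu_eml(table, self.feature_set, self.weights,
                              self.f_irq or EML_EVENT_RATE_HZ,
                              self.use_gyro, gyro_duty=duty)
            p_gyro = table.p_gyro_uw * duty
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return PowerBudget(table.p_idle_uw, table.p_accel_uw, p_gyro, p_mcu,
                           table.e_bat_j)

    def accuracy(self) -> float:
        return weighted_accuracy(self.a_s1, self.a_s2,
                                 self.weights.as_tuple())


def _reference_feature_sets():
    # default priced feature subsets of the reduced models: Stage 1 always,
    # branch extras at their band occupancy, gyro feature on the Moderate duty
    w = OccupancyWeights()
    stage1 = {"acc_max_x": 1.0, "ima": 1.0, "acc_min_y": 1.0}
    extras = {"acc_mean_y": w.sedentary, "acc_mean_z": w.sedentary,
              "acc_var_x": w.moderate, "acc_median_x": w.moderate,
              "acc_var_y": w.rigorous}
    acc_only = {**stage1, **extras}
    with_gyro = {**acc_only, "gyr_mean_x": 1.0}  # scaled by gyro_duty inside
    return acc_only, with_gyro


def reference_operating_points() -> list[OperatingPoint]:
    """The four benchmark configurations of the trade-off study.

    Per-stage accuracies are the reference measurements of the full
    (off-board) and reduced (on-board) models on the 9-activity task; they
    are inputs to the trade-off model, not recomputed here.
    """
    acc_only, with_gyro = _reference_feature_sets()
    return [
        OperatingPoint("RAW Acc", "raw", 0.965, (0.990, 0.814, 0.932)),
        OperatingPoint("RAW Acc + Gyr", "raw", 0.975, (0.993, 0.967, 0.949),
                       use_gyro=True),
        OperatingPoint("EML Acc", "eml", 0.956, (0.963, 0.667, 0.800),
                       feature_set=acc_only),
        OperatingPoint("EML Acc + Gyr", "eml", 0.956, (0.963, 0.959, 0.800),
                       use_gyro=True, feature_set=with_gyro),
    ]


def tradeoff_report(configs, table: EnergyTable | None = None) -> pd.DataFrame:
    """Accuracy / power / lifetime table, one row per operating point."""
    table = table or EnergyTable()
    rows = []
    for op in configs:
        budget = op.power(table)
        rows.append({
            "label": op.label,
            "accuracy_pct": as_percent(op.accuracy()),
            "power_uw": budget.total_uw,
            "lifetime_days": budget.lifetime_days,
        })
    return pd.DataFrame(rows, columns=["label", "accuracy_pct", "power_uw",
                                       "lifetime_days"])


def tradeoff_plot(report: pd.DataFrame, path) -> None:
    """Scatter of weighted accuracy against lifetime, one point per config."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report["lifetime_days"], report["accuracy_pct"])
    for _, row in report.iterrows():
        ax.annotate(row["label"], (row["lifetime_days"], row["accuracy_pct"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("lifetime [days]")
    ax.set_ylabel("weighted accuracy [%]")
    ax.set_title("Accuracy vs lifetime")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "RAW_EVENT_RATE_HZ",
    "EML_EVENT_RATE_HZ",
    "SECONDS_PER_DAY",
    "EnergyTable",
    "OccupancyWeights",
    "PowerBudget",
    "p_mcu_raw",
    "p_mcu_eml",
    "lifetime",
    "OperatingPoint",
    "reference_operating_points",
    "tradeoff_report",
    "tradeoff_plot",
]
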