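"""Acquisition protocols and scan-time arithmetic.

A :class:`ProtocolParams` describes one fast-spin-echo (FSE) sequence of the
gated/ungated carotid protocol family: repetition time, echo time, the double
inversion recovery (DIR) inversion time, echo train length (ETL), averages
(NEX), phase-encode count, and slices acquired per pass.  Gated sequences set
TR to an integer multiple of the subject's R-R interval, so their nominal
``tr_ms`` is interpreted at a 60 bpm reference heart rate.

Per-slice scan time follows the standard FSE bookkeeping

    T_slice = (N_pe / ETL) * NEX * TR / slices_per_pass

with the fractional shot count deliberately *not* rounded up; this reproduces
the quoted per-slice times of multi-slice protocols whose phase-encode count
is not a multiple of the ETL (256/12 = 21.33 shots).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .exceptions import InvalidParameterError

__all__ = [
    "ProtocolParams",
    "scan_time_per_slice",
    "T1W_UNGATED",
    "T1W_GATED",
    "T2W_UNGATED",
    "T2W_GATED",
    "NOISE_SCAN",
    "DEFAULT_PROTOCOLS",
]


@dataclass(frozen=True)
class ProtocolParams:
    """One sequence of the multi-contrast carotid protocol.

    ``signal_scale`` is a net amplitude efficiency factor used by the phantom
    simulator to emulate SNR penalties (multi-slice cross-talk, readout
    differences) that are not modeled mechanistically.
    """

    name: str
    tr_ms: float
    te_ms: float
    ti_ms: float | None
    etl: int
    nex: int
    n_phase_encodes: int
    slices_per_pass: int = 1
    gated: bool = False
    rr_multiple: int = 1
    signal_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.te_ms <= 0:
            raise InvalidParameterError(f"{self.name}: timing values must be > 0")
        if self.ti_ms is not None and self.ti_ms <= 0:
            raise InvalidParameterError(f"{self.name}: ti_ms must be > 0 or None")
        if self.etl < 1 or self.etl > self.n_phase_encodes:
            raise InvalidParameterError(f"{self.name}: need 1 <= etl <= n_phase_encodes")
        if self.nex < 1 or self.n_phase_encodes < 1:
            raise InvalidParameterError(f"{self.name}: nex and n_phase_encodes must be >= 1")
        if self.slices_per_pass < 1:
            raise InvalidParameterError(f"{self.name}: slices_per_pass must be >= 1")
        if self.rr_multiple < 1:
            raise InvalidParameterError(f"{self.name}: rr_multiple must be >= 1")
        if self.signal_scale < 0:
            raise InvalidParameterError(f"{self.name}: signal_scale must be >= 0")

    def shots_per_image(self) -> int:
        """Number of excitations contributing to one image (rounded)."""
        return int(round(self.n_phase_encodes / self.etl * self.nex))

    def with_(self, **kw) -> "ProtocolParams":
        return replace(self, **kw)


def scan_time_per_slice(protocol: ProtocolParams, heart_rate_bpm: float | None = None) -> float:
    """Per-slice scan time in seconds.

    Gated protocols require a heart rate; their TR is ``rr_multiple * 60/HR``
    seconds.  Fractional shot counts are kept fractional (see module docs).
    """
    if protocol.gated:
        if heart_rate_bpm is None:
            raise InvalidParameterError(
                f"{protocol.name}: gated protocol needs heart_rate_bpm for scan time"
            )
        if heart_rate_bpm <= 0:
            raise InvalidParameterError("heart_rate_bpm must be > 0")
        tr_s = protocol.rr_multiple * 60.0 / heart_rate_bpm
    else:
        tr_s = protocol.tr_ms / 1000.0
    shots = protocol.n_phase_encodes / protocol.etl * protocol.nex
    return shots * tr_s / protocol.slices_per_pass


# Default protocol set: 3T carotid multi-contrast black-blood FSE at
# 10 cm FOV / 256 matrix (0.390625 mm in-plane), 2 mm slices, plus the
# zero-RF-amplitude gradient-echo noise-only scan acquired at fixed gain.
# Inversion times null a ~1.6 s blood T1 at each nominal TR.
T1W_UNGATED = ProtocolParams(
    name="T1W-ungated", tr_ms=800.0, te_ms=13.3, ti_ms=350.0, etl=10, nex=3,
    n_phase_encodes=256, slices_per_pass=1, gated=False, signal_scale=0.80,
)
T1W_GATED = ProtocolParams(
    name="T1W-gated", tr_ms=1000.0, te_ms=13.3, ti_ms=425.0, etl=10, nex=3,
    n_phase_encodes=256, slices_per_pass=1, gated=True, rr_multiple=1,
)
T2W_UNGATED = ProtocolParams(
    name="T2W-ungated", tr_ms=2500.0, te_ms=50.0, ti_ms=805.0, etl=12, nex=3,
    n_phase_encodes=256, slices_per_pass=4, gated=False, signal_scale=0.65,
)
T2W_GATED = ProtocolParams(
    name="T2W-gated", tr_ms=2000.0, te_ms=50.0, ti_ms=706.0, etl=12, nex=3,
    n_phase_encodes=256, slices_per_pass=1, gated=True, rr_multiple=2,
)
NOISE_SCAN = ProtocolParams(
    name="noise-GRE", tr_ms=20.0, te_ms=5.7, ti_ms=None, etl=1, nex=3,
    n_phase_encodes=256, slices_per_pass=1, gated=False,
)

DEFAULT_PROTOCOLS: dict[str, ProtocolParams] = {
    p.name: p for p in (T1W_UNGATED, T1W_GATED, T2W_UNGATED, T2W_GATED, NOISE_SCAN)
}
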