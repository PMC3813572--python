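"""Container and plain-text / EDF I/O for multichannel time-series recordings.

A recording is a (time samples x channels) real matrix with a sampling rate and
an ordered list of unique channel labels (10-20 montage names for the built-in
fixtures).  All estimators in the package consume this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Standard 10-20 electrode names used for synthetic fixtures, in montage order.
TEN_TWENTY_LABELS = [
    "Fp1", "Fp2", "Fpz", "F3", "F4", "Fz", "F7", "F8",
    "C3", "Cz", "C4", "Cp5", "Cp6",
    "P7", "P3", "Pz", "O1",
    "P8", "P4", "O2",
    "T7", "T8", "Oz",
]


class UnsupportedFormatError(ValueError):
    """Raised for files the reader cannot represent (e.g. mixed-rate EDF)."""


@dataclass
class MultichannelRecording:
    """Multichannel time series: rows are time samples, columns are channels.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Real amplitudes, arbitrary units. Must be finite.
    sampling_rate : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        Unique channel names, one per column.
    meta : dict
        Free-form provenance (e.g. the generator seed); written to the sidecar.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (samples x channels) array")
        n, k = self.data.shape
        if k < 2:
            raise ValueError("a recording needs at least 2 channels")
        if n <= 10 * k:
            raise ValueError(
                f"too few samples ({n}) for {k} channels; need n_samples > 10 x n_channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or infinite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != k:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {k} data columns"
            )
        if len(set(self.channel_labels)) != k:
            raise ValueError("channel labels must be unique")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def label_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.channel_labels)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> Path:
        """Write as TSV (header row = labels) plus a ``.meta.yaml`` sidecar.

        The sidecar carries the sampling rate and any generator metadata so the
        matrix round-trips losslessly through :meth:`from_tsv`.
        """
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")
        sidecar = {"sampling_rate": float(self.sampling_rate), **self.meta}
        _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=True))
        return path

    @classmethod
    def from_tsv(cls, path, sampling_rate: float | None = None) -> "MultichannelRecording":
        """Read a TSV recording; the rate comes from the sidecar unless given."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta: dict = {}
        side = _sidecar_path(path)
        if side.exists():
            meta = yaml.safe_load(side.read_text()) or {}
        if sampling_rate is None:
            sampling_rate = meta.pop("sampling_rate", None)
        else:
            meta.pop("sampling_rate", None)
        if sampling_rate is None:
            raise ValueError(
                f"no sampling rate: pass sampling_rate= or provide sidecar {side.name}"
            )
        return cls(df.to_numpy(dtype=float), float(sampling_rate),
                   list(df.columns), meta=meta)

    @classmethod
    def from_edf(cls, path) -> "MultichannelRecording":
        """Read a European Data Format (EDF) file via :mod:`mne`.

        EDF allows a different number of samples per data record for each
        signal (i.e. per-channel sampling rates); such files cannot be
        represented as a single rectangular matrix and raise
        :class:`UnsupportedFormatError`.
        """
        path = Path(path)
        _check_edf_uniform_rate(path)
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data().T  # mne returns (channels, samples)
        return cls(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.yaml")


def _check_edf_uniform_rate(path: Path) -> None:
    """Scan the EDF header; reject files whose signals have unequal rates."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise UnsupportedFormatError(f"{path}: truncated EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise UnsupportedFormatError(f"{path}: malformed EDF header") from exc
        sig_header = fh.read(ns * 256)
    # per-signal fields are laid out field-by-field; samples-per-record is the
    # 8-byte ascii field at offset 216*ns within the signal header block
    off = 216 * ns
    spr = []
    for i in range(ns):
        raw = sig_header[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip()
        spr.append(int(raw))
    # annotation channels are allowed to differ; only compare data signals
    labels = [
        sig_header[16 * i: 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    data_spr = [s for s, lab in zip(spr, labels) if "EDF Annotations" not in lab]
    if len(set(data_spr)) > 1:
        raise UnsupportedFormatError(
            f"{path}: per-channel sampling rates differ "
            f"(samples/record: {sorted(set(data_spr))}); not supported"
        )
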