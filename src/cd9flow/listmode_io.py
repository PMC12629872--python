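"""Reading, validating and writing flow-cytometry listmode event tables.

An :class:`EventTable` holds one sample's per-event intensities on linear
(arbitrary fluorescence / scatter) scale together with a channel -> marker
mapping resolved through a :class:`PanelConfig`.  Two on-disk formats are
supported: plain CSV event tables (header row of channel names) and FCS
3.0/3.1 list-mode files, for which a small reader/writer pair is included
($PnN short names and $PnS stain names are both honoured as alias sources).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_MARKERS",
    "EventTable",
    "PanelConfig",
    "ValidationReport",
    "PanelError",
    "read_events",
    "write_events",
    "validate_panel",
]

#: Markers every analysable sample must carry.  FSC_A / FSC_H exist solely so
#: that ratio-based doublet exclusion is implementable; they are not part of
#: the staining panel.
REQUIRED_MARKERS: tuple[str, ...] = (
    "CD9", "CD10", "CD19", "CD20", "CD22", "CD24", "CD34", "CD38", "CD58",
    "CD45", "SSC", "FSC_A", "FSC_H",
)


class PanelError(ValueError):
    """A required marker could not be resolved to a channel."""


def _default_alias_patterns() -> dict[str, tuple[str, ...]]:
    pats: dict[str, tuple[str, ...]] = {}
    for m in REQUIRED_MARKERS:
        if m.startswith("CD"):
            # word-boundary so CD9 never matches CD90
            pats[m] = (rf"(?<![A-Za-z0-9]){m}(?![0-9])",)
    pats["SSC"] = (r"(?<![A-Za-z])SSC?([-_ ]?(A|INT))?(?![A-Za-z])",)
    pats["FSC_A"] = (r"(?<![A-Za-z])FSC?[-_ ]?(A|INT)(?![A-Za-z])",)
    pats["FSC_H"] = (r"(?<![A-Za-z])FSC?[-_ ]?(H|PEAK)(?![A-Za-z])",)
    return pats


@dataclass(frozen=True)
class PanelConfig:
    """Which markers a panel requires and how channel names map to them."""

    required_markers: tuple[str, ...] = REQUIRED_MARKERS
    channel_aliases: dict[str, tuple[str, ...]] = field(
        default_factory=_default_alias_patterns
    )
    intensity_scale: str = "linear"

    def resolve(
        self,
        channel_names: list[str],
        stain_names: dict[str, str] | None = None,
    ) -> dict[str, str]:
        """Map each required marker to a channel name.

        A channel matches a marker when the marker's alias pattern matches
        either the channel name itself or its stain name (FCS $PnS).
        Raises :class:`PanelError` when a marker resolves to no channel.
        """
        stain_names = stain_names or {}
        marker_map: dict[str, str] = {}
        missing: list[str] = []
        for marker in self.required_markers:
            pats = self.channel_aliases.get(
                marker, (rf"(?<![A-Za-z0-9]){re.escape(marker)}(?![A-Za-z0-9])",)
            )
            hit = None
            for ch in channel_names:
                texts = (ch, stain_names.get(ch, ""))
                if any(re.search(p, t, re.IGNORECASE) for p in pats for t in texts):
                    hit = ch
                    break
            if hit is None:
                missing.append(marker)
            else:
                marker_map[marker] = hit
        if missing:
            raise PanelError(f"missing required marker(s): {', '.join(missing)}")
        return marker_map


@dataclass
class EventTable:
    """Per-event scatter and marker intensities for one sample."""

    sample_id: str
    data: np.ndarray                       # (n_events, n_channels), float64
    channel_names: list[str]
    marker_map: dict[str, str]             # marker -> channel name
    specimen: str = "marrow"               # {"marrow", "blood"}
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            self.data = self.data.reshape(-1, len(self.channel_names))
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.marker_map.values())) != len(self.marker_map):
            raise ValueError("marker_map is not injective")
        unknown = set(self.marker_map.values()) - set(self.channel_names)
        if unknown:
            raise ValueError(f"marker_map references unknown channels: {unknown}")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def marker(self, name: str) -> np.ndarray:
        """Column of intensities for a marker (view, not copy)."""
        try:
            ch = self.marker_map[name]
        except KeyError:
            raise PanelError(f"marker {name!r} not in marker_map") from None
        return self.data[:, self.channel_names.index(ch)]

    def subset(self, indices: np.ndarray) -> "EventTable":
        """New table restricted to the given event rows (order preserved)."""
        return replace(self, data=self.data[np.asarray(indices)])


@dataclass(frozen=True)
class ValidationReport:
    n_events: int
    missing_markers: tuple[str, ...]
    nonpositive_fraction: dict[str, float]

    @property
    def ok(self) -> bool:
        return not self.missing_markers


def validate_panel(table: EventTable, panel: PanelConfig | None = None) -> ValidationReport:
    """Report-only check: missing markers and nonpositive-value fractions."""
    panel = panel or PanelConfig()
    missing = tuple(m for m in panel.required_markers if m not in table.marker_map)
    nonpos = {}
    n = max(table.n_events, 1)
    for ch_idx, ch in enumerate(table.channel_names):
        nonpos[ch] = float(np.count_nonzero(table.data[:, ch_idx] <= 0)) / n
    return ValidationReport(table.n_events, missing, nonpos)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    channels = [str(c) for c in df.columns]
    try:
        data = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if data.size and not np.isfinite(data).all():
        raise ValueError(f"non-finite value in {path}")
    return data, channels


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 (list mode, $DATATYPE F/D/I)
# ---------------------------------------------------------------------------

_FCS_DELIM = "/"


def _read_fcs(path: Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r} in {path}")

    def hdr_int(segment: bytes) -> int:
        s = segment.strip()
        return int(s) if s else 0

    text_beg = hdr_int(raw[10:18])
    text_end = hdr_int(raw[18:26])
    text = raw[text_beg : text_end + 1].decode("utf-8", "replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kw = {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
    }
    par = int(kw["$PAR"])
    tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    data_beg = hdr_int(raw[26:34]) or int(kw["$BEGINDATA"])
    data_end = hdr_int(raw[34:42]) or int(kw["$ENDDATA"])
    bits = int(kw.get("$P1B", "32"))
    if dtype_code == "F":
        np_dtype = np.dtype(f"{endian}f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(f"{endian}f8")
    elif dtype_code == "I":
        np_dtype = np.dtype(f"{endian}u{bits // 8}")
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    buf = raw[data_beg : data_end + 1]
    values = np.frombuffer(buf, dtype=np_dtype, count=par * tot)
    data = values.reshape(tot, par).astype(np.float64)
    channels = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, par + 1)]
    stains = {
        channels[i - 1]: kw[f"$P{i}S"]
        for i in range(1, par + 1)
        if f"$P{i}S" in kw
    }
    return data, channels, stains


def _write_fcs(path: Path, data: np.ndarray, channels: list[str]) -> None:
    par = len(channels)
    tot = data.shape[0]
    payload = np.ascontiguousarray(data, dtype="<f4").tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(par),
        "$TOT": str(tot),
    }
    for i, ch in enumerate(channels, start=1):
        if _FCS_DELIM in ch:
            raise ValueError(f"channel name {ch!r} contains the keyword delimiter")
        kw[f"$P{i}N"] = ch
        kw[f"$P{i}S"] = ch
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    # fixed-width data offsets so the text length is stable when filled in
    kw["$BEGINDATA"] = "0" * 10
    kw["$ENDDATA"] = "0" * 10
    def render(d: dict[str, str]) -> str:
        return _FCS_DELIM + _FCS_DELIM.join(
            x for pair in d.items() for x in pair
        ) + _FCS_DELIM

    header_len = 58
    text = render(kw)
    text_beg = header_len
    text_end = text_beg + len(text) - 1
    data_beg = text_end + 1
    data_end = data_beg + len(payload) - 1 if payload else data_beg
    kw["$BEGINDATA"] = str(data_beg).rjust(10, "0")
    kw["$ENDDATA"] = str(data_end).rjust(10, "0")
    text = render(kw)

    header = b"FCS3.1    " + b"".join(
        str(x).rjust(8).encode("ascii")
        for x in (
            text_beg,
            text_end,
            data_beg if data_beg <= 99_999_999 else 0,
            data_end if data_end <= 99_999_999 else 0,
            0,
            0,
        )
    )
    assert len(header) == header_len
    path.write_bytes(header + text.encode("utf-8") + payload)


# ---------------------------------------------------------------------------
# public IO
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "fcs"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_events(
    path: str | Path,
    format: str | None = None,
    panel: PanelConfig | None = None,
    sample_id: str | None = None,
    specimen: str = "marrow",
) -> EventTable:
    """Read a CSV or FCS listmode file into an :class:`EventTable`.

    The marker map is resolved through ``panel`` aliases; a file whose
    channels cannot cover the required panel raises :class:`PanelError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    panel = panel or PanelConfig()
    stains: dict[str, str] = {}
    if fmt == "csv":
        data, channels = _read_csv(path)
    elif fmt == "fcs":
        data, channels, stains = _read_fcs(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    marker_map = panel.resolve(channels, stains)
    return EventTable(
        sample_id=sample_id or path.stem,
        data=data,
        channel_names=channels,
        marker_map=marker_map,
        specimen=specimen,
    )


def write_events(table: EventTable, path: str | Path, format: str | None = None) -> Path:
    """Write an :class:`EventTable` to CSV or FCS (round-trips via read_events)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.DataFrame(table.data, columns=table.channel_names)
        df.to_csv(path, index=False, float_format="%.8g")
    elif fmt == "fcs":
        _write_fcs(path, table.data, table.channel_names)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
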