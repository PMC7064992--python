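"""Spectrum and library I/O plus the peptide-ion text notation.

Peptide ions are written as ``SEQ/charge_nmods[/pos,aa,name]*`` — e.g.
``SQQQEPLVCASYQSYFK/3_1/9,C,Carbamidomethyl`` — with 1-based modification
positions throughout, both in code and in every text format this package
reads or writes (the NIST convention for ``Mods=`` is 0-based; our MSP files
carry an explicit header comment declaring the 1-based dialect).

Queries travel as MGF (one file per gel fraction, fraction id ``F1``..``F10``
parsed from the TITLE); libraries as an MSP dialect with ``Name:``,
``PrecursorMZ:``, a ``Comment:`` carrying ``Mods=`` and optional ``GVP=`` /
``Decoy=`` annotations, and a ``Num peaks:`` peak table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mgf as _mgf

from .chem_masses import MassLedger, default_ledger, ppm_window

__all__ = [
    "Peak",
    "Spectrum",
    "PeptideIon",
    "LibraryEntry",
    "parse_ion_notation",
    "format_ion_notation",
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum: peak arrays sorted by m/z plus metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    charge: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if len(self.mz) and np.any(self.mz <= 0):
            raise ValueError("non-positive m/z")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self._merge_duplicates()

    def _merge_duplicates(self) -> None:
        # downstream scoring assumes distinct centroids
        if len(self.mz) < 2:
            return
        uniq, inverse = np.unique(self.mz, return_inverse=True)
        if len(uniq) == len(self.mz):
            return
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, self.intensity)
        self.mz, self.intensity = uniq, summed

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def neutral_mass(self) -> float:
        from .chem_masses import PROTON_MASS

        return self.precursor_mz * self.charge - self.charge * PROTON_MASS

    @property
    def fraction(self) -> str | None:
        return self.metadata.get("fraction")

    def __len__(self) -> int:
        return len(self.mz)


ModSpec = tuple[int | str, str, str]  # (1-based position or terminus, residue, name)


@dataclass(frozen=True)
class PeptideIon:
    """Peptide sequence + charge + localized modifications (1-based positions)."""

    sequence: str
    charge: int
    mods: tuple[ModSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        for pos, aa, name in self.mods:
            if isinstance(pos, int):
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(
                        f"mod position {pos} outside 1..{len(self.sequence)} "
                        f"in {self.sequence}"
                    )
                if self.sequence[pos - 1] != aa:
                    raise ValueError(
                        f"mod clause {pos},{aa},{name}: residue at position "
                        f"{pos} of {self.sequence} is {self.sequence[pos - 1]}"
                    )
            elif pos not in ("N-term", "C-term"):
                raise ValueError(f"bad mod position {pos!r}")

    @property
    def notation(self) -> str:
        return format_ion_notation(self)

    def neutral_mass(self, ledger: MassLedger | None = None) -> float:
        ledger = ledger or default_ledger()
        return ledger.peptide_mass(
            self.sequence, [(pos, name) for pos, _aa, name in self.mods]
        )

    def precursor_mz(self, ledger: MassLedger | None = None) -> float:
        from .chem_masses import PROTON_MASS

        return (self.neutral_mass(ledger) + self.charge * PROTON_MASS) / self.charge


_ION_RE = re.compile(r"^([A-Z]+)/(\d+)_(\d+)((?:/[^/]+)*)$")


def parse_ion_notation(text: str) -> PeptideIon:
    """Parse ``SEQ/charge_nmods[/pos,aa,name]*`` into a :class:`PeptideIon`."""
    m = _ION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed peptide-ion notation: {text!r}")
    seq, charge, nmods, rest = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
    clauses = [c for c in rest.split("/") if c]
    if len(clauses) != nmods:
        raise ValueError(
            f"{text!r}: declares {nmods} mods but has {len(clauses)} clauses"
        )
    mods: list[ModSpec] = []
    for clause in clauses:
        parts = [p.strip() for p in clause.split(",")]
        if len(parts) != 3:
            raise ValueError(f"{text!r}: bad mod clause {clause!r}")
        pos_txt, aa, name = parts
        pos: int | str = pos_txt if pos_txt in ("N-term", "C-term") else int(pos_txt)
        mods.append((pos, aa, name))
    return PeptideIon(seq, charge, tuple(mods))


def format_ion_notation(ion: PeptideIon) -> str:
    parts = [f"{ion.sequence}/{ion.charge}_{len(ion.mods)}"]
    for pos, aa, name in ion.mods:
        parts.append(f"{pos},{aa},{name}")
    return "/".join(parts)


@dataclass
class LibraryEntry:
    """One library record: a peptide ion with its reference spectrum."""

    ion: PeptideIon
    spectrum: Spectrum
    annotations: dict = field(default_factory=dict)

    @property
    def entry_id(self) -> str:
        return self.ion.notation

    @property
    def is_decoy(self) -> bool:
        return bool(self.annotations.get("Decoy"))

    @property
    def gvp(self) -> str | None:
        return self.annotations.get("GVP")

    def validate_precursor(self, ledger: MassLedger, tol_ppm: float = 20.0) -> None:
        theo = self.ion.precursor_mz(ledger)
        if abs(theo - self.spectrum.precursor_mz) > ppm_window(theo, tol_ppm):
            raise ValueError(
                f"{self.entry_id}: stored precursor {self.spectrum.precursor_mz:.4f} "
                f"outside {tol_ppm} ppm of theoretical {theo:.4f}"
            )


# -- MSP ---------------------------------------------------------------------

_MSP_HEADER = (
    "# gvpscan MSP dialect: Mods= positions are 1-based "
    "(NIST libraries use 0-based)\n"
)


def _mods_field(ion: PeptideIon) -> str:
    if not ion.mods:
        return "0"
    return str(len(ion.mods)) + "".join(
        f"/{pos},{aa},{name}" for pos, aa, name in ion.mods
    )


def write_msp(entries: list[LibraryEntry], path) -> None:
    """Write library entries in the package's MSP dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write(_MSP_HEADER)
        for e in entries:
            fh.write(f"Name: {e.ion.notation}\n")
            fh.write(f"PrecursorMZ: {e.spectrum.precursor_mz:.6f}\n")
            comment = [f"Charge={e.ion.charge}", f"Mods={_mods_field(e.ion)}"]
            for key, value in sorted(e.annotations.items()):
                comment.append(f"{key}={value}")
            if "precursor_intensity" in e.spectrum.metadata:
                comment.append(
                    f"PrecursorIntensity={e.spectrum.metadata['precursor_intensity']:.1f}"
                )
            fh.write("Comment: " + " ".join(comment) + "\n")
            fh.write(f"Num peaks: {len(e.spectrum)}\n")
            for mz, inten in zip(e.spectrum.mz, e.spectrum.intensity):
                fh.write(f"{mz:.6f} {inten:.1f}\n")
            fh.write("\n")


def read_msp(path, validate: bool = True) -> list[LibraryEntry]:
    """Read an MSP library written in the package dialect.

    Truncated entries, peak-count mismatches and ``Mods=`` fields that
    disagree with the Name suffix are rejected with the entry name.
    """
    entries = []
    with open(path) as fh:
        block: dict[str, str] = {}
        peaks: list[tuple[float, float]] = []

        def flush():
            if not block:
                return
            name = block.get("Name", "<unnamed>")
            if expecting_holder[0] != 0:
                raise ValueError(
                    f"MSP entry {name}: expected {block.get('Num peaks')} peaks, "
                    f"got {len(peaks)}"
                )
            entries.append(_build_entry(block, peaks, validate))
            block.clear()
            peaks.clear()

        expecting_holder = [0]
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                if not line:
                    flush()
                continue
            if ":" in line and not expecting_holder[0]:
                key, _, value = line.partition(":")
                key, value = key.strip(), value.strip()
                block[key] = value
                if key == "Num peaks":
                    expecting_holder[0] = int(value)
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(
                        f"MSP entry {block.get('Name', '<unnamed>')}: "
                        f"bad peak line {line!r}"
                    )
                peaks.append((float(parts[0]), float(parts[1])))
                expecting_holder[0] -= 1
        flush()
    return entries


def _build_entry(
    block: dict[str, str], peaks: list[tuple[float, float]], validate: bool
) -> LibraryEntry:
    name = block.get("Name")
    if not name:
        raise ValueError("MSP entry without a Name field")
    if "Num peaks" not in block:
        raise ValueError(f"MSP entry {name}: truncated (no Num peaks)")
    ion = parse_ion_notation(name)
    comment = block.get("Comment", "")
    fields = dict(
        kv.split("=", 1) for kv in comment.split() if "=" in kv
    )
    if validate and "Mods" in fields and fields["Mods"] != _mods_field(ion):
        raise ValueError(
            f"MSP entry {name}: Mods= field {fields['Mods']!r} disagrees "
            f"with Name suffix"
        )
    annotations = {
        k: v
        for k, v in fields.items()
        if k not in ("Charge", "Mods", "PrecursorIntensity")
    }
    if annotations.get("GVP"):
        # GVP names contain a space; re-extract from the raw comment
        m = re.search(r"GVP=(\S+ \S+)", comment)
        if m:
            annotations["GVP"] = m.group(1)
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    metadata = {}
    if "PrecursorIntensity" in fields:
        metadata["precursor_intensity"] = float(fields["PrecursorIntensity"])
    spectrum = Spectrum(
        np.array(mz), np.array(inten),
        precursor_mz=float(block.get("PrecursorMZ", 0) or 0),
        charge=ion.charge,
        metadata=metadata,
    )
    return LibraryEntry(ion, spectrum, annotations)


# -- MGF ---------------------------------------------------------------------

_FRACTION_RE = re.compile(r"\b(F(?:10|[1-9]))\b")


def read_mgf(path) -> list[Spectrum]:
    """Read query spectra from MGF; fraction id is parsed from the TITLE.

    Blocks without a PEPMASS are skipped with a warning rather than failing
    the whole run.
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block["params"]
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                warnings.warn(
                    f"{path}: skipping spectrum without PEPMASS "
                    f"(title={params.get('title', '?')!r})"
                )
                continue
            charge = int(params["charge"][0]) if params.get("charge") else 1
            metadata = {"source_file": str(path)}
            title = params.get("title", "")
            if title:
                metadata["title"] = title
                m = _FRACTION_RE.search(title)
                if m:
                    metadata["fraction"] = m.group(1)
            if "rtinseconds" in params:
                metadata["rt_min"] = float(params["rtinseconds"]) / 60.0
            if len(pepmass) > 1 and pepmass[1] is not None:
                metadata["precursor_intensity"] = float(pepmass[1])
            spectra.append(
                Spectrum(
                    np.asarray(block["m/z array"], dtype=float),
                    np.asarray(block["intensity array"], dtype=float),
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    metadata=metadata,
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write spectra as MGF (6-decimal m/z, 1-decimal intensity)."""
    blocks = []
    for i, s in enumerate(spectra):
        params = {
            "title": s.metadata.get("title", f"spectrum_{i}"),
            "pepmass": (
                round(s.precursor_mz, 6),
                round(s.metadata.get("precursor_intensity", 0.0), 1),
            ),
            "charge": f"{s.charge}+",
        }
        if "rt_min" in s.metadata:
            params["rtinseconds"] = round(s.metadata["rt_min"] * 60.0, 3)
        blocks.append(
            {
                "m/z array": np.round(s.mz, 6),
                "intensity array": np.round(s.intensity, 1),
                "params": params,
            }
        )
    _mgf.write(blocks, str(path), file_mode="w")
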