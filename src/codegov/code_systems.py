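"""Standard code systems: syntax validation, JLAC-10 parsing, master lookup.

Three code systems are supported, one per clinical domain:

* **HOT** — Japanese drug product reference codes; all-digit, 13 digits in
  the full form (a 9-digit short form can be enabled via config).
* **JLAC-10** — Japanese clinical laboratory test codes; 17 digits composed
  of five positional elements (analyte, identification, specimen,
  measurement method, result identification).
* **ICD-10** — WHO disease classification; a letter, two digits, and an
  optional dot-separated sub-classification of up to two alphanumerics.

A :class:`StandardMaster` is the authoritative code→canonical-name table for
one system; its constructor enforces that every code passes the system's
syntax validator, so downstream lookups never see a malformed key.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union


class CodeSystemId(str, Enum):
    """The three standard code systems under governance."""

    DRUG_HOT = "DRUG_HOT"
    LAB_JLAC10 = "LAB_JLAC10"
    DISEASE_ICD10 = "DISEASE_ICD10"


#: Fixed element widths of a JLAC-10 code, in order:
#: analyte, identification, specimen, method, result identification.
JLAC10_WIDTHS = (5, 4, 3, 3, 2)

#: ICD-10: letter, two digits, optional dot + up to two alphanumerics.
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.?[0-9A-Z]{1,2})?$")

#: JLAC-10: 17 positions; the analyte element's second position may be a
#: letter, every other position is a digit.
_JLAC10_RE = re.compile(r"^[0-9][0-9A-Z][0-9]{15}$")


@dataclass(frozen=True)
class SyntaxConfig:
    """Tunable syntax rules.

    hot_lengths: accepted all-digit lengths for HOT codes (13 is the full
    product code; 9 is the short form some institutions register).
    jlac10_widths: element widths; must sum to 17.
    """

    hot_lengths: tuple[int, ...] = (13,)
    jlac10_widths: tuple[int, ...] = JLAC10_WIDTHS

    def __post_init__(self) -> None:
        if sum(self.jlac10_widths) != 17 or len(self.jlac10_widths) != 5:
            raise ValueError("jlac10_widths must be five widths summing to 17")
        if not self.hot_lengths:
            raise ValueError("hot_lengths must be non-empty")


DEFAULT_SYNTAX = SyntaxConfig()
#: Syntax accepting both the 13-digit and the 9-digit HOT forms.
HOT9_SYNTAX = SyntaxConfig(hot_lengths=(13, 9))


@dataclass(frozen=True)
class Verdict:
    """Outcome of a syntax check: ``valid`` plus a reason when malformed."""

    valid: bool
    reason: str = ""

    def __bool__(self) -> bool:  # allows `if validate_code_syntax(...)`
        return self.valid


def normalize_code_text(code: str) -> str:
    """Trim and unify full-width characters to half-width (NFKC).

    Japanese EMR exports routinely mix full-width digits into code fields;
    the mix is presentation noise, not a semantic difference.
    """
    return unicodedata.normalize("NFKC", code).strip().upper()


def validate_code_syntax(
    code: str,
    system: CodeSystemId,
    config: SyntaxConfig = DEFAULT_SYNTAX,
) -> Verdict:
    """Check whether *code* is syntactically well-formed for *system*.

    Returns a :class:`Verdict`; malformed verdicts carry a short machine
    readable reason (``empty``, ``length``, ``non-digit``, ``pattern``).
    Purely syntactic — master membership is a separate step
    (:func:`lookup_master`).
    """
    text = normalize_code_text(code)
    if not text:
        return Verdict(False, "empty")
    if system is CodeSystemId.DRUG_HOT:
        if not text.isdigit():
            return Verdict(False, "non-digit")
        if len(text) not in config.hot_lengths:
            return Verdict(False, "length")
        return Verdict(True)
    if system is CodeSystemId.LAB_JLAC10:
        if len(text) != 17:
            return Verdict(False, "length")
        # 17 positions, digits throughout except the analyte element's
        # second position, which the standard allows to be a letter
        # (e.g. albumin's analyte code 3A015).
        if not _JLAC10_RE.match(text):
            return Verdict(False, "non-digit")
        return Verdict(True)
    if system is CodeSystemId.DISEASE_ICD10:
        if _ICD10_RE.match(text):
            return Verdict(True)
        return Verdict(False, "pattern")
    raise ValueError(f"unknown code system: {system!r}")


class MalformedCodeError(ValueError):
    """A code failed syntax validation where a valid code was required."""

    def __init__(self, code: str, system: CodeSystemId, reason: str):
        self.code, self.system, self.reason = code, system, reason
        super().__init__(f"malformed {system.value} code {code!r}: {reason}")


@dataclass(frozen=True)
class Jlac10Code:
    """A JLAC-10 laboratory code split into its five elements.

    Two locally identical test names (e.g. "albumin") may carry distinct
    codes differing only in specimen or method, which is why the elements
    are kept addressable rather than treating the code as opaque text.
    """

    analyte: str
    identification: str
    specimen: str
    method: str
    result_id: str

    _FIELDS = ("analyte", "identification", "specimen", "method", "result_id")

    def __post_init__(self) -> None:
        for name, width in zip(self._FIELDS, JLAC10_WIDTHS):
            value = getattr(self, name)
            ok = len(value) == width and (
                re.fullmatch(r"[0-9][0-9A-Z][0-9]{3}", value)
                if name == "analyte"
                else value.isdigit()
            )
            if not ok:
                raise ValueError(
                    f"JLAC-10 element {name} must be {width} valid characters, got {value!r}"
                )

    def serialize(self) -> str:
        """Concatenate the five elements back into the 17-digit code."""
        return "".join(getattr(self, f) for f in self._FIELDS)


def parse_jlac10(code: str, config: SyntaxConfig = DEFAULT_SYNTAX) -> Jlac10Code:
    """Split a 17-digit JLAC-10 code into its five positional elements.

    Raises :class:`MalformedCodeError` naming the failed check on invalid
    input. ``parse_jlac10(c).serialize() == c`` for every valid code.
    """
    text = normalize_code_text(code)
    verdict = validate_code_syntax(text, CodeSystemId.LAB_JLAC10, config)
    if not verdict:
        raise MalformedCodeError(code, CodeSystemId.LAB_JLAC10, verdict.reason)
    parts = []
    offset = 0
    for width in config.jlac10_widths:
        parts.append(text[offset : offset + width])
        offset += width
    return Jlac10Code(*parts)


@dataclass(frozen=True)
class LookupResult:
    present: bool
    canonical_name: Optional[str] = None


@dataclass
class StandardMaster:
    """Authoritative code → canonical name table for one code system."""

    system: CodeSystemId
    entries: dict[str, str] = field(default_factory=dict)
    version_date: Optional[date] = None
    syntax: SyntaxConfig = DEFAULT_SYNTAX

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for code, name in self.entries.items():
            text = normalize_code_text(code)
            verdict = validate_code_syntax(text, self.system, self.syntax)
            if not verdict:
                raise MalformedCodeError(code, self.system, verdict.reason)
            if text in cleaned:
                raise ValueError(f"duplicate master code {text!r}")
            cleaned[text] = name
        self.entries = cleaned

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return normalize_code_text(code) in self.entries


def lookup_master(code: str, master: StandardMaster) -> LookupResult:
    """Membership check against a standard master.

    A syntactically malformed code raises :class:`MalformedCodeError` rather
    than reporting absence: "not a code at all" and "a valid code the
    standards body has not issued" are different governance findings.
    """
    text = normalize_code_text(code)
    verdict = validate_code_syntax(text, master.system, master.syntax)
    if not verdict:
        raise MalformedCodeError(code, master.system, verdict.reason)
    if text in master.entries:
        return LookupResult(True, master.entries[text])
    return LookupResult(False)


# ---------------------------------------------------------------------------
# Master file I/O: UTF-8 CSV, header `system,code,name,version_date`.

MASTER_HEADER = ["system", "code", "name", "version_date"]


def read_masters(
    path: Union[str, Path],
    syntax: SyntaxConfig = DEFAULT_SYNTAX,
) -> dict[CodeSystemId, StandardMaster]:
    """Load one or more standard masters from a combined CSV file.

    Rows are grouped by their ``system`` tag, so one file may carry a single
    system or all three.
    """
    path = Path(path)
    per_system: dict[CodeSystemId, dict[str, str]] = {}
    dates: dict[CodeSystemId, Optional[date]] = {}
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != MASTER_HEADER:
            raise ValueError(f"{path}: expected header {','.join(MASTER_HEADER)}")
        for i, row in enumerate(reader, start=2):
            try:
                system = CodeSystemId(row["system"])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: unknown system {row['system']!r}") from exc
            per_system.setdefault(system, {})[row["code"]] = row["name"]
            if row.get("version_date"):
                dates[system] = date.fromisoformat(row["version_date"])
    return {
        system: StandardMaster(system, entries, dates.get(system), syntax)
        for system, entries in per_system.items()
    }


def write_masters(
    masters: Iterable[StandardMaster], path: Union[str, Path]
) -> None:
    """Write masters to the combined CSV format, deterministically ordered."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MASTER_HEADER)
        for master in sorted(masters, key=lambda m: m.system.value):
            stamp = master.version_date.isoformat() if master.version_date else ""
            for code in sorted(master.entries):
                writer.writerow([master.system.value, code, master.entries[code], stamp])
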