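"""Mapping observations to the SR-domain template and CSV output.

The SR-domain template is a configurable ordered list of fields, each
populated from an observation field, a constant, or left empty; the
default is an 11-field subset (the full commercial template is licensed
and not reproduced).  The pipeline emits two CSV files: the observations
themselves and their SR-domain projection.

CSV dialect is frozen — comma delimiter, double-quote quoting, LF line
endings — so outputs are bit-reproducible.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

from .model import ConfigurationError, Observation

OBS_COLUMNS = ["obs_id", "section", "domain", "test_name", "manifestation",
               "finding", "specimen", "sex", "group", "dose_value",
               "dose_unit", "treatment_related", "sentence_ids",
               "evidence_text", "noncontrolled_flags"]

#: observation attribute behind each CSV column
_OBS_FIELDS = {
    "obs_id": "obs_id", "section": "section", "domain": "domain_code",
    "test_name": "study_test", "manifestation": "manifestation",
    "finding": "finding", "specimen": "specimen", "sex": "sex",
    "group": "group", "dose_value": "dose_value", "dose_unit": "dose_unit",
    "treatment_related": "treatment_related", "sentence_ids": "sentence_ids",
    "evidence_text": "evidence_text",
    "noncontrolled_flags": "noncontrolled_flags",
}

DEFAULT_TEMPLATE_FIELDS = [
    ("SECTION", "obs:section"),
    ("DOMAIN", "obs:domain_code"),
    ("TEST_NAME", "obs:study_test"),
    ("MANIFESTATION", "obs:manifestation"),
    ("FINDING", "obs:finding"),
    ("SPECIMEN", "obs:specimen"),
    ("SEX", "obs:sex"),
    ("GROUP", "obs:group"),
    ("DOSE", "obs:dose"),
    ("TREATMENT_RELATED", "obs:treatment_related"),
    ("EVIDENCE_TEXT", "obs:evidence_text"),
]

_TEMPLATE_SOURCES = {"section", "domain_code", "study_test", "manifestation",
                     "finding", "specimen", "sex", "group", "dose",
                     "dose_value", "dose_unit", "treatment_related",
                     "evidence_text", "obs_id"}


@dataclass
class SRTemplate:
    """Ordered field -> rule mapping; rules are ``obs:<field>``,
    ``const:<text>`` or ``empty``."""

    fields: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for name, rule in self.fields:
            if rule == "empty" or rule.startswith("const:"):
                continue
            if rule.startswith("obs:") and rule[4:] in _TEMPLATE_SOURCES:
                continue
            raise ConfigurationError(
                f"template field {name!r}: unknown rule {rule!r}")

    @property
    def field_names(self) -> list[str]:
        return [name for name, _ in self.fields]

    @classmethod
    def default(cls) -> "SRTemplate":
        return cls(fields=list(DEFAULT_TEMPLATE_FIELDS))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SRTemplate":
        fields = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, rule = line.split("\t")
            fields.append((name, rule))
        return cls(fields=fields)


SRDomainRecord = dict  # ordered field-name -> value mapping


def _render(obs: Observation, source: str) -> str:
    if source == "dose":
        if obs.dose_value is None:
            return ""
        return f"{obs.dose_value:g} {obs.dose_unit}"
    value = getattr(obs, source)
    if value is None:
        return ""
    if source == "treatment_related":
        return "Yes" if value else "No"
    if source == "dose_value":
        return f"{value:g}"
    return str(value)


def map_to_sr(obs: Observation, template: SRTemplate | None = None) -> SRDomainRecord:
    """Populate each template field per its rule; unmappable fields stay
    empty, never dropped."""
    template = template or SRTemplate.default()
    record: SRDomainRecord = {}
    for name, rule in template.fields:
        if rule == "empty":
            record[name] = ""
        elif rule.startswith("const:"):
            record[name] = rule[6:]
        else:
            record[name] = _render(obs, rule[4:])
    return record


def _obs_sort_key(obs: Observation):
    try:
        major, minor = obs.obs_id.split(".")
        return (0, int(major), int(minor))
    except (ValueError, AttributeError):
        return (1, 0, 0)


def observation_to_row(obs: Observation) -> list[str]:
    row = []
    for col in OBS_COLUMNS:
        value = getattr(obs, _OBS_FIELDS[col])
        if value is None:
            row.append("")
        elif col == "treatment_related":
            row.append("true" if value else "false")
        elif col == "sentence_ids":
            row.append(";".join(str(i) for i in value))
        elif col == "noncontrolled_flags":
            row.append(";".join(value))
        elif col == "dose_value":
            row.append(f"{value:g}")
        else:
            row.append(str(value))
    return row


def observation_from_row(row: dict[str, str]) -> Observation:
    def opt(col: str):
        return row[col] if row[col] != "" else None

    return Observation(
        obs_id=row["obs_id"],
        section=row["section"],
        domain_code=row["domain"],
        study_test=opt("test_name"),
        manifestation=opt("manifestation"),
        finding=opt("finding"),
        specimen=opt("specimen"),
        sex=opt("sex"),
        group=opt("group"),
        dose_value=float(row["dose_value"]) if row["dose_value"] else None,
        dose_unit=opt("dose_unit"),
        treatment_related=row["treatment_related"] == "true",
        sentence_ids=[int(i) for i in row["sentence_ids"].split(";") if i],
        evidence_text=row["evidence_text"],
        noncontrolled_flags=[f for f in row["noncontrolled_flags"].split(";") if f],
    )


def _writer(fh):
    return csv.writer(fh, delimiter=",", quotechar='"',
                      quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def observations_to_csv(observations: list[Observation]) -> str:
    buf = io.StringIO()
    w = _writer(buf)
    w.writerow(OBS_COLUMNS)
    for obs in sorted(observations, key=_obs_sort_key):
        w.writerow(observation_to_row(obs))
    return buf.getvalue()


def read_observations_csv(path: str | Path) -> list[Observation]:
    with Path(path).open(encoding="utf-8", newline="") as fh:
        return [observation_from_row(row) for row in csv.DictReader(fh)]


def records_to_csv(records: list[SRDomainRecord],
                   template: SRTemplate | None = None) -> str:
    template = template or SRTemplate.default()
    buf = io.StringIO()
    w = _writer(buf)
    w.writerow(template.field_names)
    for rec in records:
        w.writerow([rec.get(name, "") for name in template.field_names])
    return buf.getvalue()


def write_outputs(observations: list[Observation],
                  records: list[SRDomainRecord],
                  out_dir: str | Path,
                  template: SRTemplate | None = None) -> tuple[Path, Path]:
    """Write observations.csv and sr_domain.csv (UTF-8, header row, rows
    ordered by obs_id); returns the two paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        obs_path = out / "observations.csv"
        sr_path = out / "sr_domain.csv"
        obs_path.write_text(observations_to_csv(observations),
                            encoding="utf-8")
        sr_path.write_text(records_to_csv(records, template),
                           encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write outputs under {out}: {exc}") from exc
    return obs_path, sr_path
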