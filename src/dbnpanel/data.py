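"""Long-format longitudinal panel data with explicit missingness.

Cells are stored as small integer codes per ``(subject, wave, variable)``.
Two sentinel codes are distinguished: ``MISSING`` (the value was not
observed) and ``ABSENT`` (the variable does not exist at that wave — it
is before the variable's first wave), because an absent cell is a
structural fact of the design, not a missing observation.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .errors import InputError
from .network import GroundKey, VariableSpec

MISSING = -1
ABSENT = -2

__all__ = ["PanelDataset", "read_panel", "write_panel", "MISSING", "ABSENT"]


class PanelDataset:
    """Subjects x waves x variables grid of categorical observations."""

    def __init__(
        self,
        subjects: list,
        variables: list[VariableSpec],
        waves: int,
        codes: np.ndarray,
    ) -> None:
        self.subjects = list(subjects)
        self.variables = list(variables)
        self.var_index = {v.name: j for j, v in enumerate(self.variables)}
        self.waves = int(waves)
        codes = np.asarray(codes, dtype=np.int16)
        if codes.shape != (len(self.subjects), self.waves, len(self.variables)):
            raise InputError(
                f"codes shape {codes.shape} != "
                f"({len(self.subjects)}, {self.waves}, {len(self.variables)})"
            )
        self.codes = codes
        self._check()

    def _check(self) -> None:
        for j, v in enumerate(self.variables):
            col = self.codes[:, :, j]
            if v.first_wave > 0 and not np.all(col[:, : v.first_wave] == ABSENT):
                raise InputError(
                    f"{v.name}: cells before first_wave {v.first_wave} must be absent"
                )
            if np.any(col[:, v.first_wave:] == ABSENT):
                raise InputError(
                    f"{v.name}: absent code after first_wave {v.first_wave}"
                )
            valid = (col >= 0) & (col < v.cardinality)
            if not np.all(valid | (col == MISSING) | (col == ABSENT)):
                raise InputError(f"{v.name}: state code out of range")

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, subjects: list, variables: list[VariableSpec], waves: int) -> "PanelDataset":
        codes = np.full((len(subjects), waves, len(variables)), MISSING, dtype=np.int16)
        for j, v in enumerate(variables):
            codes[:, : v.first_wave, j] = ABSENT
        return cls(subjects, variables, waves, codes)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def n_missing(self) -> int:
        return int(np.sum(self.codes == MISSING))

    def observable_cells(self) -> int:
        return int(np.sum(self.codes != ABSENT))

    def missing_rate(self) -> float:
        return self.n_missing() / max(self.observable_cells(), 1)

    def get(self, subject_pos: int, wave: int, variable: str) -> str | None:
        """Observed state label, or None when missing.  Raises on absent."""
        code = int(self.codes[subject_pos, wave, self.var_index[variable]])
        if code == ABSENT:
            raise InputError(f"{variable} is structurally absent at wave {wave}")
        if code == MISSING:
            return None
        return self.variables[self.var_index[variable]].states[code]

    def record_evidence(self, subject_pos: int) -> dict[GroundKey, str]:
        """All observed cells of one subject as ``(variable, wave) -> state``."""
        out: dict[GroundKey, str] = {}
        for j, v in enumerate(self.variables):
            for t in range(v.first_wave, self.waves):
                code = int(self.codes[subject_pos, t, j])
                if code >= 0:
                    out[(v.name, t)] = v.states[code]
        return out

    def record_missing(self, subject_pos: int) -> list[GroundKey]:
        out = []
        for j, v in enumerate(self.variables):
            for t in range(v.first_wave, self.waves):
                if self.codes[subject_pos, t, j] == MISSING:
                    out.append((v.name, t))
        return sorted(out)

    def subset(self, subject_positions) -> "PanelDataset":
        pos = list(subject_positions)
        return PanelDataset(
            [self.subjects[i] for i in pos],
            self.variables,
            self.waves,
            self.codes[pos].copy(),
        )

    # ------------------------------------------------------------------
    def to_dataframe(self, missing_token: str = "NA") -> pd.DataFrame:
        """One row per subject x wave; absent cells are empty strings."""
        rows = []
        for i, sid in enumerate(self.subjects):
            for t in range(self.waves):
                row: dict = {"subject_id": sid, "wave": t}
                for j, v in enumerate(self.variables):
                    code = int(self.codes[i, t, j])
                    if code == ABSENT:
                        row[v.name] = ""
                    elif code == MISSING:
                        row[v.name] = missing_token
                    else:
                        row[v.name] = v.states[code]
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        variables: list[VariableSpec],
        missing_token: str = "NA",
    ) -> "PanelDataset":
        required = {"subject_id", "wave"}
        if not required <= set(df.columns):
            raise InputError(f"panel needs columns {sorted(required)}")
        for v in variables:
            if v.name not in df.columns:
                raise InputError(f"panel is missing a column for variable {v.name!r}")
        waves = int(df["wave"].max()) + 1
        if int(df["wave"].min()) < 0:
            raise InputError("wave indices must be >= 0")
        subjects = list(dict.fromkeys(df["subject_id"].tolist()))
        spos = {s: i for i, s in enumerate(subjects)}
        ds = cls.empty(subjects, variables, waves)
        bad: list[str] = []
        for _, row in df.iterrows():
            i = spos[row["subject_id"]]
            t = int(row["wave"])
            for j, v in enumerate(variables):
                raw = row[v.name]
                text = "" if (raw is None or (isinstance(raw, float) and np.isnan(raw))) else str(raw)
                if t < v.first_wave:
                    continue  # structurally absent; content ignored
                if text == missing_token or text == "":
                    ds.codes[i, t, j] = MISSING
                elif text in v.states:
                    ds.codes[i, t, j] = v.states.index(text)
                else:
                    bad.append(
                        f"subject {row['subject_id']!r} wave {t} column {v.name}: "
                        f"unknown state {text!r}"
                    )
                    if len(bad) >= 10:
                        raise InputError("malformed cells:\n" + "\n".join(bad))
        if bad:
            raise InputError("malformed cells:\n" + "\n".join(bad))
        return ds

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PanelDataset)
            and self.subjects == other.subjects
            and self.variables == other.variables
            and self.waves == other.waves
            and np.array_equal(self.codes, other.codes)
        )


def write_panel(dataset: PanelDataset, path, missing_token: str = "NA") -> None:
    dataset.to_dataframe(missing_token).to_csv(path, index=False)


def read_panel(
    path,
    variables: list[VariableSpec],
    missing_token: str = "NA",
) -> PanelDataset:
    if isinstance(path, io.StringIO):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["wave"] = df["wave"].astype(int)
    return PanelDataset.from_dataframe(df, variables, missing_token)
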