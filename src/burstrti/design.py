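"""Measurement-burst study design: sessions nested in annual waves.

The reference design mirrors a four-year burst study in which participants
complete five biweekly sessions at baseline and four biweekly sessions in
each of the three subsequent years (up to 17 assessments), with two
response-time tasks (CRT, a four-choice spatial task, and BRT, its one-back
variant) administered at every session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CRT = "CRT"
BRT = "BRT"
TASKS = (CRT, BRT)


class DesignError(ValueError):
    """Raised for inconsistent burst-design configuration."""


@dataclass(frozen=True)
class BurstDesign:
    """Layout of a measurement-burst study.

    Parameters
    ----------
    n_persons : int
        Number of participants enrolled at baseline.
    n_years : int
        Number of annual burst waves.
    sessions_per_year : tuple of int
        Biweekly sessions within each annual wave (baseline year first).
    trials_per_session : int
        Analyzed trials per task per session.  BRT administers one extra
        unanalyzed leading trial (no response is possible on trial 1).
    followup_years : tuple of int
        Study years at which cognitive status is (re-)assessed beyond the
        burst waves.
    """

    n_persons: int = 304
    n_years: int = 4
    sessions_per_year: tuple[int, ...] = (5, 4, 4, 4)
    trials_per_session: int = 60
    tasks: tuple[str, ...] = TASKS
    followup_years: tuple[int, ...] = (4, 8)

    def __post_init__(self) -> None:
        if len(self.sessions_per_year) != self.n_years:
            raise DesignError(
                f"sessions_per_year has length {len(self.sessions_per_year)}, "
                f"expected n_years={self.n_years}"
            )
        counts = (self.n_persons, self.n_years, self.trials_per_session,
                  *self.sessions_per_year)
        if any(int(c) <= 0 for c in counts):
            raise DesignError("all design counts must be positive")
        for task in self.tasks:
            if task not in TASKS:
                raise DesignError(f"unknown task {task!r}")

    @property
    def total_sessions(self) -> int:
        """Maximum number of assessments per person across all waves."""
        return int(sum(self.sessions_per_year))

    def administered_trials(self, task: str) -> int:
        """Trials presented per session (BRT includes the unanalyzed trial 1)."""
        return self.trials_per_session + (1 if task == BRT else 0)

    def possible_trials(self, year: int, task: str = CRT,
                        n_persons: int | None = None) -> int:
        """Analyzable trials possible for one task in one study year.

        ``year`` is 1-based.  The count is trials × sessions × persons and
        excludes BRT's structural first trial (never analyzable).
        """
        if not 1 <= year <= self.n_years:
            raise IndexError(f"year {year} outside 1..{self.n_years}")
        if task not in self.tasks:
            raise DesignError(f"task {task!r} not in design")
        n = self.n_persons if n_persons is None else n_persons
        return self.trials_per_session * self.sessions_per_year[year - 1] * n

    def session_grid(self):
        """Iterate (year, session) pairs, both 1-based."""
        for year, n_sess in enumerate(self.sessions_per_year, start=1):
            for session in range(1, n_sess + 1):
                yield year, session


def generate_design(config: dict | None = None) -> BurstDesign:
    """Build a :class:`BurstDesign` from a plain config mapping."""
    config = dict(config or {})
    if "sessions_per_year" in config:
        config["sessions_per_year"] = tuple(config["sessions_per_year"])
    if "followup_years" in config:
        config["followup_years"] = tuple(config["followup_years"])
    if "tasks" in config:
        config["tasks"] = tuple(config["tasks"])
    if "sessions_per_year" in config and "n_years" not in config:
        config["n_years"] = len(config["sessions_per_year"])
    return BurstDesign(**config)


def possible_trials(design: BurstDesign, year: int, task: str = CRT,
                    n_persons: int | None = None) -> int:
    return design.possible_trials(year, task, n_persons)
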