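"""Pluggable notification interface for run status and errors.

The batch orchestrator reports through an abstract sink so that messaging
adapters (chat webhooks, e-mail, ...) can be plugged in without touching the
run logic. The default sink writes to the package logger; a collecting sink
is provided for tests and for building the run log.
"""

from __future__ import annotations

import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass

from .errors import ValidationError

SEVERITIES = ("info", "warning", "error")


@dataclass(frozen=True)
class Notification:
    severity: str
    message: str
    sample: str | None = None
    phase: str | None = None
    attachment: str | None = None  # e.g. path to a rendered figure

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValidationError(f"severity must be one of {SEVERITIES}, got {self.severity!r}")
        if self.severity == "error" and not (self.sample and self.phase):
            raise ValidationError("error notifications must name the sample and phase")

    def format(self) -> str:
        ctx = ""
        if self.sample:
            ctx = f" [{self.sample}" + (f"/{self.phase}]" if self.phase else "]")
        return f"{self.severity.upper()}{ctx}: {self.message}"


class NotificationSink(ABC):
    @abstractmethod
    def notify(self, notification: Notification) -> None: ...

    def info(self, message: str, **kwargs) -> None:
        self.notify(Notification("info", message, **kwargs))

    def warning(self, message: str, **kwargs) -> None:
        self.notify(Notification("warning", message, **kwargs))

    def error(self, message: str, *, sample: str, phase: str, **kwargs) -> None:
        self.notify(Notification("error", message, sample=sample, phase=phase, **kwargs))


class LoggingSink(NotificationSink):
    """Default sink: forwards to the package logger."""

    _LEVELS = {"info": logging.INFO, "warning": logging.WARNING, "error": logging.ERROR}

    def __init__(self, logger: logging.Logger | None = None):
        self._logger = logger or logging.getLogger("facsort.run")

    def notify(self, notification: Notification) -> None:
        self._logger.log(self._LEVELS[notification.severity], notification.format())


class CollectingSink(NotificationSink):
    """Accumulates notifications in memory (tests, run logs)."""

    def __init__(self):
        self.messages: list[Notification] = []

    def notify(self, notification: Notification) -> None:
        self.messages.append(notification)

    def of_severity(self, severity: str) -> list[Notification]:
        return [n for n in self.messages if n.severity == severity]


class TeeSink(NotificationSink):
    """Fan a notification out to several sinks (e.g. log file + collector)."""

    def __init__(self, *sinks: NotificationSink):
        self.sinks = sinks

    def notify(self, notification: Notification) -> None:
        for sink in self.sinks:
            sink.notify(notification)
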