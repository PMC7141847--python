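"""Named method lists and the wrapper contract.

A pipeline step (normalization, imputation, clustering, ...) is represented
by a :class:`MethodList`: an ordered, named collection of transforms that all
accept the step's common input type and return its common output type. The
benchmark machinery expands a table row into one row per method in the list.

Methods with tuning constants bind them at registration (partial
application), keeping the step signature uniform: every registered transform
is a one-argument callable.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Any, Callable, Iterator, Mapping, Optional, Sequence

from .errors import RegistrationError

__all__ = ["Method", "MethodList", "make_method_list", "wrap_method"]

Transform = Callable[[Any], Any]

_FORBIDDEN = set(",\n\r")


def _check_name(name: str) -> None:
    if not isinstance(name, str) or not name:
        raise RegistrationError("method names must be non-empty strings")
    if _FORBIDDEN & set(name):
        raise RegistrationError(
            f"method name {name!r} contains characters illegal in CSV output"
        )


@dataclass(frozen=True)
class Method:
    """A single named transform within a pipeline step.

    ``fn`` must be pure with respect to the benchmark table: it may not
    mutate its input value. ``params`` records constants bound at
    registration, for provenance only.
    """

    name: str
    fn: Transform
    params: Optional[Mapping[str, Any]] = None

    def __post_init__(self) -> None:
        _check_name(self.name)
        if not callable(self.fn):
            raise RegistrationError(f"method {self.name!r}: fn is not callable")

    def __call__(self, value: Any) -> Any:
        return self.fn(value)


@dataclass(frozen=True)
class MethodList:
    """Ordered, named collection of same-signature transforms for one step.

    ``step_name`` becomes the column header recording which method produced
    each benchmark row. ``validator``, when given, is called on every method
    output and may raise to signal a contract violation (captured as a
    per-row failure downstream).
    """

    step_name: str
    methods: tuple[Method, ...]
    validator: Optional[Callable[[Any], None]] = None

    def __post_init__(self) -> None:
        if not self.step_name or not isinstance(self.step_name, str):
            raise RegistrationError("step_name must be a non-empty string")
        methods = tuple(self.methods)
        if not methods:
            raise RegistrationError(f"step {self.step_name!r}: empty method list")
        names = [m.name for m in methods]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistrationError(
                f"step {self.step_name!r}: duplicate method names {sorted(dupes)}"
            )
        object.__setattr__(self, "methods", methods)

    def __iter__(self) -> Iterator[Method]:
        return iter(self.methods)

    def __len__(self) -> int:
        return len(self.methods)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.methods)


def make_method_list(
    step_name: str,
    entries: Mapping[str, Transform] | Sequence[tuple[str, Transform]],
    validator: Optional[Callable[[Any], None]] = None,
) -> MethodList:
    """Build a :class:`MethodList` from ``name -> transform`` entries.

    Entry order is preserved (dicts iterate in insertion order). Duplicate
    or CSV-unsafe names raise :class:`RegistrationError`.
    """
    if isinstance(entries, Mapping):
        items = list(entries.items())
    else:
        items = list(entries)
        names = [n for n, _ in items]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistrationError(
                f"step {step_name!r}: duplicate method names {sorted(dupes)}"
            )
    methods = tuple(Method(name=n, fn=f) for n, f in items)
    return MethodList(step_name=step_name, methods=methods, validator=validator)


def wrap_method(
    fn: Transform,
    pre_adapter: Optional[Transform] = None,
    post_adapter: Optional[Transform] = None,
) -> Transform:
    """Adapt a core method to a step's input/output contract.

    Returns ``x -> post_adapter(fn(pre_adapter(x)))``; omitted adapters are
    identities. Adapter exceptions surface as the wrapped method's failure
    and are captured per-row by ``apply_methods``, never raised to the
    caller of the benchmark.
    """

    @functools.wraps(fn)
    def wrapped(value: Any) -> Any:
        if pre_adapter is not None:
            value = pre_adapter(value)
        value = fn(value)
        if post_adapter is not None:
            value = post_adapter(value)
        return value

    return wrapped
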