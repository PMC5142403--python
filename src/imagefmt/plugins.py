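"""Plugin registry, application context, and the gateway facade.

Every functional component — formats, translators, filters, services — is
registered in a :class:`Context` as a :class:`PluginDescriptor` carrying a
numeric priority. All resolution order in the framework (checker polling,
translator lookup, filter stacking) derives from that single number:
higher priority is consulted earlier, with lexicographic identity as the
deterministic tie-break. Contexts are fully isolated from one another.

Third-party formats are discovered through the standard packaging
entry-point mechanism (group ``imagefmt.formats``): installing a
distribution that advertises a :class:`~imagefmt.formats.Format` makes it
available to every application in the environment without any code change
here. A broken external declaration is logged and skipped, never fatal.

The :class:`Gateway` is the convenience facade most callers use: detect,
parse, open a filtered reader, convert.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional

from .errors import DuplicatePluginError, ValidationError
from .filters import FilePattern, FilterStack, parse_file_pattern
from .formats import (
    DatasetMetadata,
    Format,
    FormatService,
    SourceRef,
    write_dataset,
)
from .translate import TranslationReport, TranslatorService

log = logging.getLogger(__name__)

ENTRY_POINT_GROUP = "imagefmt.formats"


class PluginType(enum.Enum):
    FORMAT = "format"
    TRANSLATOR = "translator"
    FILTER = "filter"
    SERVICE = "service"


@dataclass(frozen=True)
class PluginDescriptor:
    """Registered component identity: name, role, priority, factory."""

    identity: str
    plugin_type: PluginType
    priority: float
    factory: Callable

    def __post_init__(self) -> None:
        if not (isinstance(self.priority, (int, float)) and math.isfinite(self.priority)):
            raise ValidationError(f"plugin priority must be finite, got {self.priority!r}")


class Context:
    """An isolated plugin registry plus its per-context service singletons."""

    def __init__(self) -> None:
        self._plugins: dict = {}
        self.services: dict = {}

    def register(self, desc: PluginDescriptor) -> None:
        if desc.identity in self._plugins:
            raise DuplicatePluginError(
                f"plugin identity {desc.identity!r} already registered"
            )
        self._plugins[desc.identity] = desc

    def has_plugin(self, identity: str) -> bool:
        return identity in self._plugins

    def plugins_of_type(self, plugin_type) -> list:
        """Snapshot of matching descriptors, sorted by (-priority, identity)."""
        matching = [d for d in self._plugins.values() if d.plugin_type == plugin_type]
        return sorted(matching, key=lambda d: (-d.priority, d.identity))

    def get_service(self, role: str):
        return self.services[role]


def register_plugin(ctx: Context, desc: PluginDescriptor) -> None:
    """Module-level alias for :meth:`Context.register`."""
    ctx.register(desc)


def plugins_of_type(ctx: Context, plugin_type) -> list:
    """Module-level alias for :meth:`Context.plugins_of_type`."""
    return ctx.plugins_of_type(plugin_type)


def register_format(ctx: Context, fmt: Format) -> None:
    """Register a Format instance under its own name and priority."""
    ctx.register(
        PluginDescriptor(fmt.name, PluginType.FORMAT, fmt.priority, lambda f=fmt: f)
    )


def _register_builtins(ctx: Context) -> None:
    from . import builtin
    from .filters import ChannelFiller, FileStitcher

    for fmt in builtin.BUILTIN_FORMATS:
        register_format(ctx, fmt)
    for tr in builtin.builtin_translators():
        ctx.register(
            PluginDescriptor(
                tr.identity, PluginType.TRANSLATOR, tr.priority, lambda t=tr: t
            )
        )
    for cls in (ChannelFiller, FileStitcher):
        ctx.register(
            PluginDescriptor(
                cls.FILTER_ID, PluginType.FILTER, cls.PRIORITY, lambda c=cls: c
            )
        )
    ctx.services["format"] = FormatService(ctx)
    ctx.services["translator"] = TranslatorService(ctx)
    for role in ("format", "translator"):
        svc = ctx.services[role]
        ctx.register(
            PluginDescriptor(
                f"{role}-service", PluginType.SERVICE, 0.0, lambda s=svc: s
            )
        )


def discover_external_plugins(ctx: Context) -> int:
    """Scan packaging entry points for third-party formats; returns count added.

    Each entry point in the ``imagefmt.formats`` group may load to a
    :class:`Format` instance, a callable returning one, or an iterable of
    them. Built-ins are never displaced: identities already registered are
    skipped. Any failure in one entry point is logged and isolated.
    """
    from importlib import metadata as importlib_metadata

    added = 0
    try:
        eps = importlib_metadata.entry_points(group=ENTRY_POINT_GROUP)
    except Exception as exc:  # pragma: no cover - environment-dependent
        log.warning("entry-point scan failed: %s", exc)
        return 0
    for ep in eps:
        try:
            obj = ep.load()
            if callable(obj) and not isinstance(obj, Format):
                obj = obj()
            fmts = [obj] if isinstance(obj, Format) else list(obj)
            for fmt in fmts:
                if not isinstance(fmt, Format):
                    raise TypeError(
                        f"entry point {ep.name!r} yielded {type(fmt).__name__}, "
                        "expected a Format"
                    )
                if ctx.has_plugin(fmt.name):
                    log.info(
                        "skipping external format %r: identity already registered",
                        fmt.name,
                    )
                    continue
                register_format(ctx, fmt)
                added += 1
        except Exception as exc:
            log.warning("ignoring malformed plugin entry point %r: %s", ep.name, exc)
    return added


class Gateway:
    """Facade over one context's services: detect, parse, open, convert."""

    def __init__(self, context: Context):
        self.context = context

    @property
    def formats(self) -> FormatService:
        return self.context.get_service("format")

    @property
    def translators(self) -> TranslatorService:
        return self.context.get_service("translator")

    def discover(self) -> int:
        """Pull in third-party formats from the packaging environment."""
        return discover_external_plugins(self.context)

    def detect(self, src, open_allowed: bool = True) -> Format:
        return self.formats.find_format(src, open_allowed)

    def parse(self, src) -> DatasetMetadata:
        return self.formats.parse(src)

    def open(self, src, fill_channels: bool = True, stitch: bool = True) -> FilterStack:
        """Detect, parse and wrap a source in the configured filter chain.

        A pattern locator (``img_<0-2>.sciraw``) is detected through its
        first file; the file-stitching filter, when enabled, presents the
        whole range as one dataset.
        """
        src = SourceRef.coerce(src)
        pattern: Optional[FilePattern] = None
        base_src = src
        if src.is_pattern():
            pattern = parse_file_pattern(src.locator)
            base_src = SourceRef(pattern.name_at(pattern.start))
        fmt = self.detect(base_src)
        meta = fmt.make_parser().parse(base_src)
        base_reader = fmt.make_reader(meta, base_src)
        specs = [
            (d.identity, d.priority, d.factory())
            for d in self.context.plugins_of_type(PluginType.FILTER)
        ]
        enabled = {}
        for fid, _, _ in specs:
            if fid == "channel-filler":
                enabled[fid] = fill_channels
            elif fid == "file-stitcher":
                enabled[fid] = stitch
        return FilterStack(
            base_reader, specs, enabled,
            pattern=pattern, fmt=fmt,
            pattern_locator=src.locator if pattern else None,
        )

    def convert(self, src, dest, output_format: Optional[str] = None,
                fill_channels: bool = True, stitch: bool = True) -> TranslationReport:
        """Read ``src`` through the filter chain and write it as ``dest``.

        Metadata is routed through the translator service (direct route if
        one is registered, otherwise through the baseline); the returned
        report enumerates any fields the destination schema dropped.
        """
        stack = self.open(src, fill_channels=fill_channels, stitch=stitch)
        dest_fmt = self.formats.writable_format_for(dest, output_format)
        dest_meta, report = self.translators.translate_to(stack.metadata, dest_fmt)
        write_dataset(
            dest_fmt, dest, dest_meta,
            (
                (i, p, stack.open_plane(i, p))
                for i in range(stack.image_count)
                for p in range(stack.plane_count(i))
            ),
        )
        return report


def create_gateway() -> Gateway:
    """A gateway over a fresh, isolated context with all built-ins registered."""
    ctx = Context()
    _register_builtins(ctx)
    return Gateway(ctx)
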