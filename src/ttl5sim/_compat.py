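"""Optional numba acceleration.

The integrator hot loop and the channel rate functions are written so they
run both as plain Python/NumPy and under numba's nopython compiler. When
numba is importable the kernel is JIT-compiled; otherwise the same code runs
(much more slowly) in the interpreter.
"""

try:  # pragma: no cover - exercised implicitly by the whole suite
    from numba import njit as _njit

    HAVE_NUMBA = True

    def maybe_njit(*args, **kwargs):
        kwargs.setdefault("cache", True)
        return _njit(*args, **kwargs)

except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def maybe_njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap
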