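"""glibc allocator tuning for large-array workloads.

Training repeatedly allocates and frees ~100 MB activation buffers. With
glibc's default mmap threshold every such buffer is unmapped on free and
page-faulted back in on the next allocation, which can dominate step time.
Raising the threshold keeps the blocks on the heap for reuse. No-op on
non-glibc platforms.
"""

from __future__ import annotations

import ctypes

_done = False


def tune_allocator() -> None:
    global _done
    if _done:
        return
    _done = True
    try:
        libc = ctypes.CDLL("libc.so.6")
        M_MMAP_THRESHOLD = -3
        libc.mallopt(M_MMAP_THRESHOLD, 1 << 30)
    except Exception:
        pass
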