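#!/usr/bin/env python
"""Fetch the deposited genome assemblies from NCBI (requires network).

Downloads the contigs of the three GenBank WGS projects used by the
benchmarks into ``data/deposited/<accession>.fasta``::

    python scripts/fetch_deposited.py

WGS master accessions have no sequence themselves; contigs follow the
``<prefix>01NNNNNNN`` scheme, so contig ids are probed incrementally until
EFetch returns nothing.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = ["JBEWZF000000000", "JBEWZG000000000", "JBEWZH000000000"]
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "deposited"
BATCH = 50
MAX_CONTIGS = 2000


def efetch_fasta(ids: list[str]) -> str:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(ids), "rettype": "fasta",
         "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as fh:
        return fh.read().decode()


def fetch_project(accession: str) -> str:
    prefix = accession[:6] + "01"
    records: list[str] = []
    i = 1
    while i <= MAX_CONTIGS:
        ids = [f"{prefix}{j:07d}" for j in range(i, i + BATCH)]
        try:
            chunk = efetch_fasta(ids).strip()
        except Exception as exc:  # noqa: BLE001 - report and stop
            print(f"  request failed at contig {i}: {exc}", file=sys.stderr)
            break
        got = chunk.count(">")
        if got == 0:
            break
        records.append(chunk)
        i += BATCH
        if got < BATCH:
            break
        time.sleep(0.4)  # NCBI rate limit
    return "\n".join(records) + ("\n" if records else "")


def main() -> int:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    ok = True
    for acc in ACCESSIONS:
        out = OUT_DIR / f"{acc}.fasta"
        if out.exists():
            print(f"{acc}: already present")
            continue
        print(f"{acc}: fetching ...")
        fasta = fetch_project(acc)
        if not fasta:
            print(f"{acc}: FAILED (no records retrieved)", file=sys.stderr)
            ok = False
            continue
        out.write_text(fasta)
        print(f"{acc}: wrote {fasta.count('>')} contigs to {out}")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
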