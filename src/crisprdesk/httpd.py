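"""Optional local HTTP facade exposing the pipeline's three endpoints.

Built on the standard library's threading HTTP server — a deliberately
thin JSON layer over :class:`~crisprdesk.orchestrator.Engine`:

* ``POST /jobs``  body ``{"gene_sequence": ..., "genome_ref": ...}``
  -> ``{"job_id": ...}`` (processing starts in a background thread)
* ``GET /jobs/<id>/progress`` -> status plus per-assessment fractions
* ``GET /jobs/<id>/results``  -> the per-candidate result records
"""
from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .orchestrator import Engine, UnknownGenomeError, UnknownJobError


def _handler_class(engine: Engine):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet by default
            pass

        def _reply(self, code: int, payload: dict) -> None:
            body = json.dumps(payload).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_POST(self) -> None:
            if self.path.rstrip("/") != "/jobs":
                self._reply(404, {"error": "not found"})
                return
            length = int(self.headers.get("Content-Length", "0"))
            try:
                req = json.loads(self.rfile.read(length) or b"{}")
                job_id = engine.submit_job(
                    req.get("gene_sequence", ""), req["genome_ref"]
                )
            except (KeyError, json.JSONDecodeError):
                self._reply(400, {"error": "expected gene_sequence and genome_ref"})
                return
            except UnknownGenomeError as exc:
                self._reply(404, {"error": str(exc)})
                return
            # the analysis spins up on demand and scales back to zero
            threading.Thread(target=engine.run, daemon=True).start()
            self._reply(202, {"job_id": job_id})

        def do_GET(self) -> None:
            parts = [p for p in self.path.split("/") if p]
            if len(parts) != 3 or parts[0] != "jobs":
                self._reply(404, {"error": "not found"})
                return
            job_id, what = parts[1], parts[2]
            try:
                if what == "progress":
                    on_frac, off_frac, status = engine.job_progress(job_id)
                    self._reply(
                        200,
                        {"status": status, "ontarget": on_frac, "offtarget": off_frac},
                    )
                elif what == "results":
                    records = engine.job_results(job_id)
                    self._reply(
                        200,
                        {
                            "job_id": job_id,
                            "results": [
                                {
                                    "record_id": r.record_id,
                                    "start": r.start,
                                    "strand": r.strand,
                                    "target23": r.target23,
                                    "accepted": r.accepted,
                                    "specificity": r.specificity,
                                    "both_complete": r.both_complete,
                                }
                                for r in records
                            ],
                        },
                    )
                else:
                    self._reply(404, {"error": "not found"})
            except UnknownJobError as exc:
                self._reply(404, {"error": str(exc)})

    return Handler


def make_server(engine: Engine, port: int = 8753) -> ThreadingHTTPServer:
    return ThreadingHTTPServer(("127.0.0.1", port), _handler_class(engine))


def serve_forever(engine: Engine, port: int = 8753) -> None:  # pragma: no cover
    make_server(engine, port=port).serve_forever()
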