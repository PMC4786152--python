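"""Self-contained HTML scrubber for a PNG frame sequence.

The viewer references frames by relative path, so the output directory can
be moved or mounted anywhere.  A slider and arrow keys scrub frame by
frame; play/pause loops at an adjustable speed in either direction.
"""

from __future__ import annotations

from pathlib import Path

from .errors import DataError

_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
  body {{ font-family: sans-serif; margin: 1.5em; background: #fafafa; }}
  #frame {{ max-width: 100%; border: 1px solid #ccc; background: white; }}
  #controls {{ margin-top: 0.7em; display: flex; gap: 0.6em; align-items: center; }}
  #slider {{ flex: 1; }}
  button {{ min-width: 3.5em; }}
</style>
</head>
<body>
<h2>{title}</h2>
<img id="frame" alt="animation frame">
<div id="controls">
  <button id="play">Play</button>
  <button id="back">&#9664;</button>
  <button id="fwd">&#9654;</button>
  <input type="range" id="slider" min="0" max="{last}" value="0" step="1">
  <span id="label"></span>
  <label>speed <select id="speed">
    <option value="250">slow</option>
    <option value="100" selected>normal</option>
    <option value="40">fast</option>
  </select></label>
  <label><input type="checkbox" id="reverse"> reverse</label>
</div>
<script>
const frames = {frames_json};
let i = 0, timer = null;
const img = document.getElementById("frame");
const slider = document.getElementById("slider");
const label = document.getElementById("label");
function show(k) {{
  i = Math.min(Math.max(k, 0), frames.length - 1);
  img.src = frames[i];
  slider.value = i;
  label.textContent = (i + 1) + " / " + frames.length;
}}
function tick() {{
  const dir = document.getElementById("reverse").checked ? -1 : 1;
  show((i + dir + frames.length) % frames.length);
}}
document.getElementById("play").onclick = function () {{
  if (timer) {{ clearInterval(timer); timer = null; this.textContent = "Play"; }}
  else {{
    timer = setInterval(tick, +document.getElementById("speed").value);
    this.textContent = "Pause";
  }}
}};
document.getElementById("speed").onchange = function () {{
  if (timer) {{ clearInterval(timer); timer = setInterval(tick, +this.value); }}
}};
document.getElementById("back").onclick = () => show(i - 1);
document.getElementById("fwd").onclick = () => show(i + 1);
slider.oninput = () => show(+slider.value);
document.addEventListener("keydown", (e) => {{
  if (e.key === "ArrowLeft") show(i - 1);
  if (e.key === "ArrowRight") show(i + 1);
}});
show(0);
</script>
</body>
</html>
"""


def write_viewer(frame_files: list, title: str, out_path) -> Path:
    """Write an HTML viewer listing the frames in order, by relative path."""
    if not frame_files:
        raise DataError("cannot build a viewer with zero frames")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rel = []
    for f in frame_files:
        f = Path(f)
        try:
            rel.append(f.relative_to(out_path.parent).as_posix())
        except ValueError:
            raise DataError(
                f"frame {f} is not under the viewer directory {out_path.parent}; "
                "the viewer requires relative paths")
    frames_json = "[" + ", ".join(f'"{p}"' for p in rel) + "]"
    html = _TEMPLATE.format(
        title=title, last=len(rel) - 1, frames_json=frames_json)
    out_path.write_text(html, encoding="utf-8")
    return out_path
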