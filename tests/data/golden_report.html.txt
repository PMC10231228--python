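<!DOCTYPE html>
<html><head><meta charset="utf-8">
<title>Attention report</title>
<style>
body { font-family: Georgia, serif; margin: 2em auto; max-width: 50em; }
.doc { margin-bottom: 2em; }
.doc h2 { font-size: 1em; font-family: monospace; }
.sent { padding: 0.15em 0.4em; margin: 0.1em 0; border-left: 0.5em solid; }
.tok { padding: 0 0.12em; border-radius: 2px; }
.lex { text-decoration: underline; }
.meta { color: #555; font-size: 0.85em; }
table.mass { border-collapse: collapse; font-size: 0.85em; }
table.mass td, table.mass th { border: 1px solid #ccc; padding: 0.2em 0.6em; }
</style></head><body>
<h1>Attention report</h1>
<p class="meta">Green shading: hierarchically normalized word weight (sentence weight x word weight), rescaled by each document&#x27;s maximum. Red left bar: sentence weight, rescaled by each document&#x27;s maximum. Underline: lexicon token.</p>
<div class="doc" id="viz-a">
<h2>viz-a <span class="meta">(predicted AD, true AD)</span></h2>
<div class="sent" style="border-left-color:rgba(200,30,30,1.000000)">
<span class="tok lex" style="background:rgba(30,160,30,1.000000)">uh</span> <span class="tok" style="background:rgba(30,160,30,0.272727)">the</span> <span class="tok lex" style="background:rgba(30,160,30,0.454545)">boy</span> <span class="tok" style="background:rgba(30,160,30,0.090909)">.</span>
</div>
<div class="sent" style="border-left-color:rgba(200,30,30,0.428571)">
<span class="tok lex" style="background:rgba(30,160,30,0.467532)">he</span> <span class="tok" style="background:rgba(30,160,30,0.233766)">falls</span> <span class="tok" style="background:rgba(30,160,30,0.077922)">.</span>
</div>
<table class="mass"><tr><th>lexicon</th><th>attention mass</th></tr><tr><td>filler</td><td>0.385000</td></tr><tr><td>pronoun</td><td>0.180000</td></tr><tr><td>seed</td><td>0.175000</td></tr></table>
</div>
<div class="doc" id="viz-b">
<h2>viz-b <span class="meta">(predicted CTRL, true CTRL)</span></h2>
<div class="sent" style="border-left-color:rgba(200,30,30,1.000000)">
<span class="tok" style="background:rgba(30,160,30,0.200000)">the</span> <span class="tok lex" style="background:rgba(30,160,30,1.000000)">window</span> <span class="tok" style="background:rgba(30,160,30,0.200000)">is</span> <span class="tok" style="background:rgba(30,160,30,0.500000)">open</span> <span class="tok" style="background:rgba(30,160,30,0.100000)">.</span>
</div>
<table class="mass"><tr><th>lexicon</th><th>attention mass</th></tr><tr><td>filler</td><td>0.000000</td></tr><tr><td>pronoun</td><td>0.000000</td></tr><tr><td>seed</td><td>0.500000</td></tr></table>
</div>
</body></html>
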