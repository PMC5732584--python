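# False-positive filters for age extraction: a candidate age match is
# discarded when any of these regexes matches the text window around it.
# One pattern per line, case-insensitive.
\bago\b
\bwhen\s+i\s+was\b
\bwhen\s+i'?m\b
\bfeel\w*\s+(like\s+)?(i'?m\s+)?\d
\bfelt\b
\bas\s+if\b
\bwish\w*\s+i\s+was\b
\blook\w*\s+(like\s+)?(i'?m\s+)?\d
\bact\w*\s+(like\s+)?(i'?m\s+)?\d
\bturn\w*\s+\d+\s+(soon|next)
\bin\s+\d+\s+years?\b
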