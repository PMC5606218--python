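<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="272" height="176" viewBox="0 0 272 176">
<rect x="0" y="0" width="272" height="176" fill="white"/>
<text x="188" y="64" text-anchor="middle" font-family="sans-serif" font-size="11">ABL1(T315I)</text>
<text x="244" y="64" text-anchor="middle" font-family="sans-serif" font-size="11">ABL1</text>
<text x="154" y="89" text-anchor="end" font-family="sans-serif" font-size="11">Chronic Myeloid Leukemia</text>
<g id="tumor:chronic myeloid leukemia:ABL1(T315I)"><line x1="164" y1="85" x2="212" y2="85" stroke="#555555" stroke-width="2"/></g>
<text x="154" y="115" text-anchor="end" font-family="sans-serif" font-size="11">axitinib</text>
<g id="cell:axitinib:ABL1(T315I)" data-state="consistent"><rect x="160" y="98" width="56" height="26" fill="none" stroke="#DDDDDD"/><rect x="164" y="103" width="10" height="16" fill="#D5E8DD"/><rect x="164" y="109" width="48" height="4" fill="black"/></g>
<g id="cell:axitinib:ABL1" data-state="dtc_only"><rect x="216" y="98" width="56" height="26" fill="none" stroke="#DDDDDD"/><line x1="222" y1="118" x2="266" y2="104" stroke="black" stroke-width="2"/></g>
<text x="154" y="141" text-anchor="end" font-family="sans-serif" font-size="11">bosutinib</text>
<g id="cell:bosutinib:ABL1(T315I)" data-state="conflicting"><rect x="160" y="124" width="56" height="26" fill="none" stroke="#DDDDDD"/><rect x="164" y="129" width="48" height="16" fill="#C0392B"/><rect x="164" y="135" width="29" height="4" fill="black"/></g>
<g id="cell:bosutinib:ABL1" data-state="missing"><rect x="216" y="124" width="56" height="26" fill="none" stroke="#DDDDDD"/></g>
<text x="154" y="167" text-anchor="end" font-family="sans-serif" font-size="11">nilotinib</text>
<g id="cell:nilotinib:ABL1(T315I)" data-state="cgi_only"><rect x="160" y="150" width="56" height="26" fill="none" stroke="#DDDDDD"/><rect x="164" y="155" width="29" height="16" fill="#82B99A"/></g>
<g id="cell:nilotinib:ABL1" data-state="missing"><rect x="216" y="150" width="56" height="26" fill="none" stroke="#DDDDDD"/></g>
</svg>
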