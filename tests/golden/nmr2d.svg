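<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800" height="400" viewBox="0 0 800 400"><rect x="0" y="0" width="800" height="400" fill="#ffffff" /><g class="series-root"><g id="series--series-1" class="series" stroke="#1b9e77"><circle cx="770.00" cy="312.09" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="764.00" cy="239.73" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="748.61" cy="238.16" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="714.96" cy="129.87" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="659.61" cy="165.20" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="656.78" cy="139.04" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="646.63" cy="54.09" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="620.94" cy="298.57" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="592.92" cy="240.17" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="511.21" cy="152.80" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="498.50" cy="150.05" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="468.15" cy="335.91" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="451.14" cy="227.81" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="443.94" cy="98.70" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="375.30" cy="107.90" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="368.67" cy="148.38" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="368.28" cy="206.03" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="342.05" cy="198.03" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="338.33" cy="84.19" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="336.89" cy="212.83" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="247.29" cy="117.65" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="178.54" cy="187.78" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="169.41" cy="284.94" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="115.88" cy="208.51" r="2.50" fill="#1b9e77" stroke="none" /><circle cx="60.00" cy="231.40" r="2.50" fill="#1b9e77" stroke="none" /></g></g><g class="axes"><line x1="60.00" y1="350.00" x2="770.00" y2="350.00" stroke="#333333" stroke-width="1.00" /><line x1="60.00" y1="40.00" x2="60.00" y2="350.00" stroke="#333333" stroke-width="1.00" /><line x1="98.21" y1="350.00" x2="98.21" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="98.21" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">9</text><line x1="177.83" y1="350.00" x2="177.83" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="177.83" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">8</text><line x1="257.44" y1="350.00" x2="257.44" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="257.44" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">7</text><line x1="337.06" y1="350.00" x2="337.06" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="337.06" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">6</text><line x1="416.68" y1="350.00" x2="416.68" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="416.68" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">5</text><line x1="496.30" y1="350.00" x2="496.30" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="496.30" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">4</text><line x1="575.92" y1="350.00" x2="575.92" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="575.92" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">3</text><line x1="655.53" y1="350.00" x2="655.53" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="655.53" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">2</text><line x1="735.15" y1="350.00" x2="735.15" y2="355.00" stroke="#333333" stroke-width="1.00" /><text x="735.15" y="367.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">1</text><line x1="55.00" y1="68.40" x2="60.00" y2="68.40" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="72.25" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">20</text><line x1="55.00" y1="106.99" x2="60.00" y2="106.99" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="110.84" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">40</text><line x1="55.00" y1="145.57" x2="60.00" y2="145.57" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="149.42" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">60</text><line x1="55.00" y1="184.16" x2="60.00" y2="184.16" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="188.01" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">80</text><line x1="55.00" y1="222.74" x2="60.00" y2="222.74" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="226.59" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">100</text><line x1="55.00" y1="261.33" x2="60.00" y2="261.33" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="265.18" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">120</text><line x1="55.00" y1="299.91" x2="60.00" y2="299.91" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="303.76" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">140</text><line x1="55.00" y1="338.49" x2="60.00" y2="338.49" stroke="#333333" stroke-width="1.00" /><text x="52.00" y="342.34" font-family="sans-serif" font-size="11.00" text-anchor="end" fill="#333333">160</text><text x="415.00" y="392.00" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333">F2 / ppm</text><text x="0" y="0" font-family="sans-serif" font-size="11.00" text-anchor="middle" fill="#333333" transform="translate(14.00,195.00) rotate(-90)">F1 / ppm</text></g></svg>
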