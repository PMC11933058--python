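>TIM3_IGV|Q8TDQ0|22-131 human TIM3 (HAVCR2) IgV ectodomain
SEVEYRAEVGQNAYLPCFYTPAAPGNLVPVCWGKGACPVFECGNVVLRTDERDVNYWTSR
YWLNGDFRKGDVSLTIENVTLADSGIYCCRIQIPGIMNDEKFNLKLVIKP
>TIGIT_IGV|Q495A1|22-141 human TIGIT (VSIG9) IgV ectodomain
MMTGTIETTGNISAEKGGSIILQCHLSSTTAQVTQVNWEQQDQLLAICNADLGWHISPSF
KDRVAPGPGLGLTLQSLTVNDTGEYFCIYHTYPDGTYTGRIFLEVLESSVAEHGARFQIP
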