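item_id,domain,question,P1,P2,P3,P4,P5,P6,P7,P8,P9
hw_instructions_clear,ease_of_use,Are the instructions on the MS-FIT hardware configuration clear to follow?,4,4,3,4,4,4,4,4,4
hw_configuration_easy,ease_of_use,Is the hardware configuration easy in practice?,4,4,4,4,4,4,4,4,2
use_instructions_clear,ease_of_use,Are the instructions on the MS-FIT use clear and easy to follow?,4,4,4,4,5,4,4,4,4
interface_pleasant,ease_of_use,Is the user interface pleasant?,4,4,4,4,4,3,4,4,3
easy_to_play,playability,Is MS-FIT easy to be played?,5,4,4,4,4,4,4,4,2
virtual_trainer_enjoyment,enjoyment,Does a virtual trainer increase the enjoyment towards exercise?,4,4,4,4,5,3,4,4,5
satisfaction,satisfaction,Are you satisfied of the experience with MS-FIT?,3,4,3,4,5,4,4,4,4
home_use_motivation,acceptance,Are you motivated to use MS-FIT autonomously at home?,3,3,3,5,5,5,5,5,5
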